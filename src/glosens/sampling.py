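"""Monte-Carlo global sensitivity analysis.

Parameters are drawn independently and uniformly on
``[ref*(1-delta), ref*(1+delta)]``; at every sampled set the full scaled
sensitivity spectrum is evaluated and recorded.  Sampled sets whose output
is undefined (lost steady state, lost oscillation) are counted and
reported, never silently dropped — the histogram is built over the defined
values only and the undefined fraction travels with every distribution
summary.

Sample ``i`` of a run depends only on ``(seed, i)`` (counter-based seed
derivation), so chunked, resumed or parallel execution reproduces the
sequential stream exactly.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import stats

from .dynamics import OutputSpec
from .model import KineticModel, ParameterDomain, ParameterSet
from .sensitivity import sensitivity_spectrum

#: Shapiro-Wilk input is capped by deterministic subsampling (the test's
#: validity range); the cap is recorded on every distribution summary.
SHAPIRO_CAP = 5000

MIN_BINS = 50
MAX_BINS = 2000


@dataclass
class SensitivityRecord:
    """One sampled parameter set and the scaled sensitivity of the output
    to one parameter there."""

    index: int
    params: ParameterSet
    parameter: str
    value: float | None
    status: str = "ok"
    reason: str = ""

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def sample_domain(domain: ParameterDomain, n: int, seed: int, start: int = 0) -> Iterator[ParameterSet]:
    """Stream ``n`` uniform draws from the parameter hypercube.

    Deterministic given ``seed``; ``start`` resumes mid-stream without
    re-drawing earlier samples.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for i in range(start, start + n):
        yield domain.sample_at(seed, i)


def run_sampling_gsa(
    model: KineticModel,
    domain: ParameterDomain,
    spec: OutputSpec,
    n: int,
    seed: int,
    parameters: Sequence[str] | None = None,
    rel_step: float = 1e-3,
    start: int = 0,
) -> dict[str, list[SensitivityRecord]]:
    """Sampled scaled-sensitivity records, keyed by parameter id.

    For each sampled set the sensitivity spectrum is computed (restricted to
    ``parameters`` when given) and one record per parameter is emitted.
    Failures at one sampled set never abort the run; they surface as
    undefined records with a reason code.
    """
    spec.validate_for(model)
    pids = list(parameters) if parameters is not None else model.parameter_ids
    records: dict[str, list[SensitivityRecord]] = {pid: [] for pid in pids}
    for i, ps in enumerate(sample_domain(domain, n, seed, start=start), start=start):
        coeffs = sensitivity_spectrum(model, ps, spec, rel_step=rel_step, parameters=pids)
        for c in coeffs:
            records[c.parameter].append(
                SensitivityRecord(i, ps, c.parameter, c.value, c.status, c.reason)
            )
    return records


def shapiro_wilk(values: Sequence[float], cap: int = SHAPIRO_CAP) -> tuple[float, float]:
    """Shapiro-Wilk normality test, deterministically subsampled to ``cap``.

    Raises ValueError below 3 values; constant input yields (nan, nan).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    if len(x) > cap:
        idx = np.unique(np.linspace(0, len(x) - 1, cap).round().astype(int))
        x = x[idx]
    if np.ptp(x) == 0.0:
        return math.nan, math.nan
    w, p = stats.shapiro(x)
    return float(w), float(p)


def silverman_smooth(
    edges: np.ndarray, densities: np.ndarray, n: int, scale: float = 1.0
) -> np.ndarray:
    """Gaussian-smooth a histogram density with Silverman's bandwidth
    (times ``scale``).

    Used by the multimodality classifier (scale 1) and to locate
    distribution peaks (scale 2: the raw modal bin of a flat-topped density
    is sampling-noise dominated, and mode estimation is stable at a larger
    bandwidth than density estimation).
    """
    from scipy.ndimage import gaussian_filter1d

    centres = 0.5 * (edges[:-1] + edges[1:])
    widths = np.diff(edges)
    counts = densities * widths * n
    mean = float(np.sum(centres * counts) / n)
    std = math.sqrt(max(float(np.sum(counts * (centres - mean) ** 2) / n), 0.0))
    cdf = np.cumsum(counts) / n
    q25 = float(np.interp(0.25, cdf, centres))
    q75 = float(np.interp(0.75, cdf, centres))
    spread = min(std, (q75 - q25) / 1.34) if q75 > q25 else std
    bw = scale * 0.9 * spread * n ** (-0.2) if spread > 0 else 0.0
    sigma_bins = bw / float(np.mean(widths)) if bw > 0 else 0.0
    if sigma_bins <= 0:
        return np.asarray(densities, dtype=float)
    return gaussian_filter1d(np.asarray(densities, dtype=float), sigma_bins, mode="constant")


def _fd_bin_count(x: np.ndarray) -> int:
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    rng = float(np.ptp(x))
    if iqr <= 0 or rng <= 0:
        return MIN_BINS
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    return int(np.clip(math.ceil(rng / width), MIN_BINS, MAX_BINS))


@dataclass
class SensitivityDistribution:
    """Histogram + summary statistics of sampled coefficients for one
    parameter at one variation band.

    The histogram is normalised to unit area over the defined samples; the
    normalised peak height is modal-bin frequency divided by the *total*
    number of samples (defined plus undefined).
    """

    parameter: str
    band: float | None
    bin_edges: np.ndarray | None
    densities: np.ndarray | None
    peak_location: float | None
    peak_height: float | None
    vmin: float | None
    vmax: float | None
    local_value: float | None
    shapiro_w: float | None
    shapiro_p: float | None
    n_ok: int
    n_undefined: int
    undefined_reasons: dict[str, int] = field(default_factory=dict)
    degenerate: bool = False
    shapiro_cap: int = SHAPIRO_CAP
    status: str = "ok"

    @property
    def n_total(self) -> int:
        return self.n_ok + self.n_undefined

    @property
    def undefined_fraction(self) -> float:
        return self.n_undefined / self.n_total if self.n_total else 0.0

    def values_summary(self) -> dict:
        return {
            "parameter": self.parameter,
            "band": self.band,
            "peak_location": self.peak_location,
            "peak_height": self.peak_height,
            "min": self.vmin,
            "max": self.vmax,
            "local_value": self.local_value,
            "shapiro_w": self.shapiro_w,
            "shapiro_p": self.shapiro_p,
            "n_ok": self.n_ok,
            "n_undefined": self.n_undefined,
            "undefined_reasons": dict(self.undefined_reasons),
            "degenerate": self.degenerate,
            "shapiro_cap": self.shapiro_cap,
            "status": self.status,
        }


def summarize_distribution(
    records: Iterable[SensitivityRecord | float],
    n_bins: int | None = None,
    band: float | None = None,
    local_value: float | None = None,
    parameter: str | None = None,
) -> SensitivityDistribution:
    """Distribution summary of sampled coefficients for one parameter.

    Accepts either :class:`SensitivityRecord` streams or plain floats (for
    synthetic distribution fixtures).  Bin count defaults to
    Freedman-Diaconis with a floor of 50 bins.
    """
    values, reasons = [], Counter()
    pid = parameter
    for r in records:
        if isinstance(r, SensitivityRecord):
            pid = pid or r.parameter
            if r.ok:
                values.append(r.value)
            else:
                reasons[r.reason or "undefined"] += 1
        else:
            values.append(float(r))
    n_ok, n_undef = len(values), sum(reasons.values())
    total = n_ok + n_undef
    if n_ok == 0:
        return SensitivityDistribution(
            pid or "?", band, None, None, None, None, None, None, local_value,
            None, None, 0, n_undef, dict(reasons), status="empty",
        )

    x = np.asarray(values, dtype=float)
    vmin, vmax = float(np.min(x)), float(np.max(x))
    # spreads at the rounding noise of the finite-difference pipeline are
    # physically constant coefficients, not distributions
    degenerate = (vmax - vmin) <= 1e-9 * max(1.0, abs(vmin), abs(vmax))
    if degenerate:
        mid = 0.5 * (vmin + vmax)
        eps = max(1e-12, abs(mid) * 1e-9, 0.5 * (vmax - vmin))
        edges = np.array([mid - eps, mid + eps])
        counts = np.array([n_ok])
    else:
        bins = n_bins if n_bins is not None else _fd_bin_count(x)
        counts, edges = np.histogram(x, bins=bins, range=(vmin, vmax))
    widths = np.diff(edges)
    densities = counts / (n_ok * widths)  # unit area over the ok samples
    if degenerate:
        modal = 0
    else:
        modal = int(np.argmax(silverman_smooth(edges, densities, n_ok, scale=2.0)))
    peak_location = float(0.5 * (edges[modal] + edges[modal + 1]))
    peak_height = float(counts[modal] / total)

    w = p = None
    if n_ok >= 3 and not degenerate:
        w, p = shapiro_wilk(x)
        if math.isnan(w):
            w = p = None
    return SensitivityDistribution(
        pid or "?", band, edges, densities, peak_location, peak_height,
        vmin, vmax, local_value, w, p, n_ok, n_undef, dict(reasons),
        degenerate=degenerate,
    )
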