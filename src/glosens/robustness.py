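"""Pattern-of-control classification and the whole-model robustness level.

A sensitivity distribution at one variation band is reduced to qualitative
pattern flags: the sign span of the attainable coefficients, whether the
support reaches zero, whether the distribution is multimodal, and whether
high-magnitude control (above a threshold, default 1) is attainable.  A
model's robustness level is the smallest variation band at which any
parameter's distribution shows multiple coexisting patterns (mixed sign,
several modes, or zero alongside clearly nonzero control): small levels mean
a fragile distribution of control, large levels a robust one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .dynamics import OutputSpec
from .errors import ConfigError
from .model import KineticModel, ParameterDomain
from .sampling import (
    SensitivityDistribution,
    run_sampling_gsa,
    silverman_smooth,
    summarize_distribution,
)
from .sensitivity import sensitivity_spectrum
from .swarm import SensitivityBounds, SwarmSettings, _sub_seed, sensitivity_bounds

ABOVE_MAX_BAND = math.inf


def _exceeds(value: float, threshold: float) -> bool:
    """Magnitude comparison with a relative tolerance absorbing
    finite-difference rounding (a structurally unit coefficient evaluates
    to 1 +/- 1e-13, which must count as magnitude 1)."""
    return value >= threshold - 1e-9 * max(1.0, abs(threshold))


@dataclass
class PatternFlags:
    sign_span: str  # "positive-only" | "negative-only" | "mixed"
    attains_zero: bool
    multimodal: bool
    mode_locations: list[float]
    high_magnitude: bool
    max_abs: float

    @property
    def multiple_patterns(self) -> bool:
        """Do several qualitative patterns of control coexist?"""
        if self.multimodal or self.sign_span == "mixed":
            return True
        # zero and clearly-nonzero control in one distribution
        scale = max(self.max_abs, 1e-12)
        return self.attains_zero and any(abs(m) > 0.05 * scale for m in self.mode_locations)


def classify_pattern(
    distribution: SensitivityDistribution,
    bounds: SensitivityBounds | None = None,
    magnitude_threshold: float = 1.0,
    prominence_fraction: float = 0.05,
    zero_window_fraction: float = 0.01,
    zero_density_floor: float = 0.01,
) -> PatternFlags:
    """Qualitative pattern flags for one sensitivity distribution.

    Optimisation bounds, when given and wider than the sampled extremes,
    extend the sign span and magnitude — but they carry no density
    information, so they can never add modes.  Multimodality is detected on
    a Gaussian-smoothed histogram (Silverman bandwidth) with a relative
    prominence criterion.
    """
    if distribution.status != "ok" or distribution.n_ok == 0:
        raise ValueError("cannot classify an empty distribution")
    vmin, vmax = distribution.vmin, distribution.vmax
    if bounds is not None and bounds.ok:
        vmin = min(vmin, bounds.lower)
        vmax = max(vmax, bounds.upper)
    span = vmax - vmin

    if distribution.degenerate:
        modes = [distribution.peak_location]
        multimodal = False
    else:
        edges, dens = distribution.bin_edges, distribution.densities
        centres = 0.5 * (edges[:-1] + edges[1:])
        smoothed = silverman_smooth(edges, dens, distribution.n_ok)
        padded = np.concatenate([[0.0], smoothed, [0.0]])  # edge modes count
        peaks, _ = find_peaks(padded, prominence=prominence_fraction * float(np.max(padded)))
        modes = [float(centres[p - 1]) for p in peaks]
        if not modes:
            modes = [distribution.peak_location]
        multimodal = len(modes) > 1

    if vmin >= 0.0:
        sign_span = "positive-only"
    elif vmax <= 0.0:
        sign_span = "negative-only"
    else:
        sign_span = "mixed"

    zero_window = zero_window_fraction * span if span > 0 else 0.0
    if distribution.degenerate:
        attains_zero = abs(distribution.peak_location) <= max(zero_window, 1e-12)
    else:
        edges, dens = distribution.bin_edges, distribution.densities
        overlap = (edges[:-1] <= zero_window) & (edges[1:] >= -zero_window)
        attains_zero = bool(
            np.any(dens[overlap] > zero_density_floor * float(np.max(dens)))
        )
    max_abs = max(abs(vmin), abs(vmax))
    return PatternFlags(
        sign_span=sign_span,
        attains_zero=attains_zero,
        multimodal=multimodal,
        mode_locations=modes,
        high_magnitude=_exceeds(max_abs, magnitude_threshold),
        max_abs=max_abs,
    )


@dataclass
class RobustnessProfile:
    """Per-band exceedance fractions, pattern flags, and the robustness
    level (smallest band with multiple coexisting patterns of control)."""

    bands: list[float]
    threshold: float
    exceedance_sampling: dict[float, float]
    exceedance_bounds: dict[float, float] | None
    flags: dict[float, dict[str, PatternFlags]]  # band -> parameter -> flags
    distributions: dict[float, dict[str, SensitivityDistribution]]
    robustness_level: float  # a band, or inf when no band shows multiple patterns
    non_viable_bands: list[float] = field(default_factory=list)
    n_per_band: int = 0
    seed: int = 0

    @property
    def robustness_level_label(self) -> str:
        return "above-max-band" if math.isinf(self.robustness_level) else str(self.robustness_level)

    def to_dict(self) -> dict:
        return {
            "bands": self.bands,
            "threshold": self.threshold,
            "n_per_band": self.n_per_band,
            "seed": self.seed,
            "robustness_level": None if math.isinf(self.robustness_level) else self.robustness_level,
            "robustness_level_label": self.robustness_level_label,
            "non_viable_bands": self.non_viable_bands,
            "exceedance_sampling": {str(b): f for b, f in self.exceedance_sampling.items()},
            "exceedance_bounds": (
                {str(b): f for b, f in self.exceedance_bounds.items()}
                if self.exceedance_bounds is not None
                else None
            ),
            "flags": {
                str(b): {
                    pid: {
                        "sign_span": fl.sign_span,
                        "attains_zero": fl.attains_zero,
                        "multimodal": fl.multimodal,
                        "mode_locations": fl.mode_locations,
                        "high_magnitude": fl.high_magnitude,
                        "max_abs": fl.max_abs,
                        "multiple_patterns": fl.multiple_patterns,
                    }
                    for pid, fl in row.items()
                }
                for b, row in self.flags.items()
            },
        }


def robustness_profile(
    model: KineticModel,
    spec: OutputSpec,
    bands: Sequence[float],
    n_per_band: int,
    seed: int = 0,
    swarm: SwarmSettings | None = None,
    threshold: float = 1.0,
    parameters: Sequence[str] | None = None,
    rel_step: float = 1e-3,
    n_bins: int | None = None,
) -> RobustnessProfile:
    """Assemble the robustness profile of one model output.

    Sampling runs at every band reuse the same master seed, so the underlying
    uniform draws are matched across bands (nested hypercubes).  When swarm
    settings are given, optimisation bounds are computed per parameter and
    band as independent evidence; they widen sign spans and exceedance but
    never add modes.
    """
    bands = [float(b) for b in bands]
    if not bands or any(b2 <= b1 for b1, b2 in zip(bands, bands[1:])):
        raise ConfigError("bands must be a non-empty strictly increasing list")
    spec.validate_for(model)
    pids = list(parameters) if parameters is not None else model.parameter_ids
    reference = model.reference_parameters()
    local = {
        c.parameter: c.value
        for c in sensitivity_spectrum(model, reference, spec, rel_step, parameters=pids)
    }

    exceed_s: dict[float, float] = {}
    exceed_b: dict[float, float] | None = {} if swarm is not None else None
    flags: dict[float, dict[str, PatternFlags]] = {}
    dists: dict[float, dict[str, SensitivityDistribution]] = {}
    non_viable: list[float] = []
    level = ABOVE_MAX_BAND

    for b_i, band in enumerate(bands):
        domain = ParameterDomain(reference, band)
        records = run_sampling_gsa(
            model, domain, spec, n_per_band, seed, parameters=pids, rel_step=rel_step
        )
        band_dists = {
            pid: summarize_distribution(
                records[pid], n_bins=n_bins, band=band, local_value=local.get(pid)
            )
            for pid in pids
        }
        dists[band] = band_dists
        usable = {pid: d for pid, d in band_dists.items() if d.status == "ok"}
        if not usable:
            non_viable.append(band)
            continue

        band_bounds: dict[str, SensitivityBounds] = {}
        if swarm is not None:
            for p_i, pid in enumerate(pids):
                sub = SwarmSettings(
                    swarm_size=swarm.swarm_size,
                    iteration_limit=swarm.iteration_limit,
                    inertia=swarm.inertia,
                    cognitive=swarm.cognitive,
                    social=swarm.social,
                    seed=_sub_seed(seed, 1 + b_i * len(pids) + p_i),
                )
                band_bounds[pid] = sensitivity_bounds(
                    model, domain, spec, pid, settings=sub, rel_step=rel_step
                )

        band_flags = {
            pid: classify_pattern(
                d, bounds=band_bounds.get(pid), magnitude_threshold=threshold
            )
            for pid, d in usable.items()
        }
        flags[band] = band_flags
        exceed_s[band] = sum(
            1 for pid, d in usable.items() if _exceeds(max(abs(d.vmin), abs(d.vmax)), threshold)
        ) / len(pids)
        if exceed_b is not None:
            exceed_b[band] = sum(
                1
                for pid, bd in band_bounds.items()
                if bd.ok and _exceeds(max(abs(bd.lower), abs(bd.upper)), threshold)
            ) / len(pids)
        if math.isinf(level) and any(f.multiple_patterns for f in band_flags.values()):
            level = band

    return RobustnessProfile(
        bands=bands,
        threshold=threshold,
        exceedance_sampling=exceed_s,
        exceedance_bounds=exceed_b,
        flags=flags,
        distributions=dists,
        robustness_level=level,
        non_viable_bands=non_viable,
        n_per_band=n_per_band,
        seed=seed,
    )
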