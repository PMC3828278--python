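<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="two_step_chain" name="two-step chain">
    <listOfFunctionDefinitions>
      <functionDefinition id="massaction">
        <math xmlns="http://www.w3.org/1998/Math/MathML">
          <lambda>
            <bvar><ci>k</ci></bvar>
            <bvar><ci>s</ci></bvar>
            <apply><times/><ci>k</ci><ci>s</ci></apply>
          </lambda>
        </math>
      </functionDefinition>
    </listOfFunctionDefinitions>
    <listOfCompartments>
      <compartment id="cell" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="X0" compartment="cell" initialConcentration="1" boundaryCondition="true"/>
      <species id="S1" compartment="cell" initialConcentration="0"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k1" value="2"/>
      <parameter id="ratefactor" value="0" constant="false"/>
    </listOfParameters>
    <listOfRules>
      <assignmentRule variable="ratefactor">
        <math xmlns="http://www.w3.org/1998/Math/MathML">
          <apply><divide/><cn>2</cn><cn>2</cn></apply>
        </math>
      </assignmentRule>
    </listOfRules>
    <listOfReactions>
      <reaction id="R1" name="first step" reversible="false">
        <listOfReactants>
          <speciesReference species="X0"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="S1"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><ci>massaction</ci><ci>k1</ci><ci>X0</ci></apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="R2" name="second step" reversible="false">
        <listOfReactants>
          <speciesReference species="S1"/>
        </listOfReactants>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><times/><ci>ratefactor</ci><ci>k1</ci><ci>S1</ci></apply>
          </math>
          <listOfParameters>
            <parameter id="k1" value="4"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
    <listOfEvents>
      <event id="noop">
        <trigger>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><gt/><ci>S1</ci><cn>100</cn></apply>
          </math>
        </trigger>
        <listOfEventAssignments>
          <eventAssignment variable="S1">
            <math xmlns="http://www.w3.org/1998/Math/MathML">
              <cn>0</cn>
            </math>
          </eventAssignment>
        </listOfEventAssignments>
      </event>
    </listOfEvents>
  </model>
</sbml>
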