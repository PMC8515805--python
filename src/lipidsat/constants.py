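"""Physical constants shared across modules."""

GAS_CONSTANT_KJ: float = 8.314e-3
"""Gas constant R in kJ/mol/K."""

SPECIES: tuple[str, ...] = ("protein", "CHOL", "POPC", "other", "solvent")
"""Recognized molecule species labels.

``protein`` — the embedded membrane protein; ``CHOL`` — the tracked sterol
ligand; ``POPC`` — the background phospholipid; ``other`` — any further lipid
species; ``solvent`` — water beads and ions.
"""
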