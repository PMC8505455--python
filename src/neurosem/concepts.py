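"""Default stimulus set: 45 physics concepts spanning classical and
post-classical domains, with the 15 elementary classical concepts that are
shared with the student cohort flagged."""

from __future__ import annotations

import pandas as pd

# (label, category, elementary). "elementary" marks the classical subset
# presented to both expert and student cohorts.
_CONCEPTS: list[tuple[str, str, bool]] = [
    # particle / nuclear physics
    ("boson", "post-classical", False),
    ("fermion", "post-classical", False),
    ("muon", "post-classical", False),
    ("neutrino", "post-classical", False),
    ("particle decay", "post-classical", False),
    # astrophysics
    ("anti-particle", "post-classical", False),
    ("cosmology", "post-classical", False),
    ("dark matter", "post-classical", False),
    ("multiverse", "post-classical", False),
    ("quasar", "post-classical", False),
    # special relativity
    ("gamma ray", "post-classical", False),
    ("inertial frame", "post-classical", False),
    ("Lorentz invariant", "post-classical", False),
    ("simultaneity", "post-classical", False),
    ("tachyon", "post-classical", False),
    # quantum mechanics
    ("coherence", "post-classical", False),
    ("commutator", "post-classical", False),
    ("duality", "post-classical", False),
    ("wave function", "post-classical", False),
    # elementary classical mechanics
    ("acceleration", "classical", True),
    ("centripetal force", "classical", True),
    ("gravity", "classical", True),
    ("torque", "classical", True),
    ("velocity", "classical", True),
    # elementary energy / electricity
    ("direct current", "classical", True),
    ("electric field", "classical", True),
    ("force", "classical", True),
    ("potential energy", "classical", True),
    ("voltage", "classical", True),
    # elementary light / sound
    ("frequency", "classical", True),
    ("light", "classical", True),
    ("radio waves", "classical", True),
    ("sound waves", "classical", True),
    ("wavelength", "classical", True),
    # classical mechanics
    ("buoyancy", "classical", False),
    ("Coriolis force", "classical", False),
    ("fractal dimension", "classical", False),
    ("Lagrangian", "classical", False),
    ("Hamiltonian", "classical", False),
    # condensed matter
    ("precession", "classical", False),
    ("canonical ensemble", "classical", False),
    ("conduction", "classical", False),
    ("crystal lattice", "classical", False),
    ("diamagnetism", "classical", False),
    ("insulator", "classical", False),
]


def default_concept_table() -> pd.DataFrame:
    """The default 45-concept stimulus table.

    Columns: ``label``, ``category`` ({classical, post-classical}),
    ``elementary`` (bool; subset shared with the student cohort) and
    ``word_length`` (character count of the label).
    """
    df = pd.DataFrame(_CONCEPTS, columns=["label", "category", "elementary"])
    df["word_length"] = df["label"].str.len()
    return df


def default_concept_labels() -> list[str]:
    return [c[0] for c in _CONCEPTS]
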