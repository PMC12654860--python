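"""Registry of condition presets for the virtual instrument.

Each preset is a truncated normal mixture over whole-cell elastic moduli
(kPa), encoding the measured stiffness distribution of one experimental
condition: the five cell-type panels, the Cytochalasin D and Trichostatin A
dose series, the trypsinization comparison, and the lamin A / progerin
overexpression panel. Single-component presets carry the reported
mean ± SD; the progerin-overexpression preset is a two-component mixture
reproducing its characteristic stiffness peaks in the 2-4 and 6-8 kPa bands,
and the lamin A preset is a right-skewed (but unimodal) mixture.

`REPORTED_N` records the number of cells measured per condition, used as the
default population size when re-running a condition virtually.
"""

from __future__ import annotations

from .virtual_instrument import PopulationPreset

__all__ = ["PRESETS", "REPORTED_N", "get_preset", "reported_n"]


def _single(name: str, mean: float, sd: float) -> PopulationPreset:
    return PopulationPreset(name=name, components=((1.0, mean, sd),))


PRESETS: dict[str, PopulationPreset] = {
    # cell-type panel
    "HEK293A": _single("HEK293A", 2.85, 1.15),
    "C2C12": _single("C2C12", 6.55, 2.46),
    "HeLa": _single("HeLa", 5.08, 1.47),
    "10T1/2": _single("10T1/2", 6.36, 1.96),
    "UE7T-13": _single("UE7T-13", 5.90, 1.60),
    # Cytochalasin D (actin depolymerization) dose series, HEK293A
    "CD_untreated": _single("CD_untreated", 3.05, 0.99),
    "CD_1uM": _single("CD_1uM", 2.81, 1.16),
    "CD_2uM": _single("CD_2uM", 2.39, 1.10),
    # Trichostatin A (HDAC inhibition) dose series, HEK293A
    "TSA_control": _single("TSA_control", 2.70, 0.86),
    "TSA_250nM": _single("TSA_250nM", 2.64, 0.92),
    "TSA_500nM": _single("TSA_500nM", 2.42, 0.76),
    # harvesting comparison
    "trypsinized": _single("trypsinized", 2.84, 1.15),
    "non_trypsinized": _single("non_trypsinized", 3.21, 1.09),
    # lamin panel: wild-type control, lamin A overexpression (right-skewed,
    # unimodal), progerin overexpression (bimodal: endogenous-cytoskeleton
    # peak at ~3 kPa plus a stiff subpopulation at ~7 kPa)
    "normal_HEK293A": _single("normal_HEK293A", 2.85, 1.15),
    "LaminA_OX": PopulationPreset(
        name="LaminA_OX",
        components=((0.70, 3.2, 1.0), (0.30, 4.6, 2.0)),
    ),
    "Progerin_OX": PopulationPreset(
        name="Progerin_OX",
        components=((0.60, 3.0, 0.8), (0.40, 7.0, 0.8)),
    ),
}

#: cells measured per condition
REPORTED_N: dict[str, int] = {
    "HEK293A": 57,
    "C2C12": 23,
    "HeLa": 16,
    "10T1/2": 31,
    "UE7T-13": 31,
    "CD_untreated": 26,
    "CD_1uM": 17,
    "CD_2uM": 29,
    "TSA_control": 30,
    "TSA_250nM": 31,
    "TSA_500nM": 26,
    "trypsinized": 57,
    "non_trypsinized": 36,
    "normal_HEK293A": 57,
    "LaminA_OX": 100,
    "Progerin_OX": 100,
}


def get_preset(name: str) -> PopulationPreset:
    """Look up a preset by condition name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def reported_n(name: str) -> int:
    """Default population size for a condition."""
    get_preset(name)
    return REPORTED_N[name]
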