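"""Before/after comparison of KS energy features under the Valsalva maneuver.

The Valsalva maneuver (forced exhalation against a closed airway)
transiently reduces venous return and cardiac output, so a paired
normal-state / maneuver recording from the same subject perturbs cardiac
ejection as a single variable.  The comparison reports, for each of the 19
energy features, its value in the normal state (Ns), under the maneuver
(Vm), and the percent variation

    V = (Ns - Vm) / Ns * 100,

so a positive V means the feature decreased under reduced cardiac output.

VALSALVA_REFERENCE bundles a published paired measurement of the 19
features for cross-checking the variation arithmetic; rows whose printed
Ns/Vm are too coarsely rounded to reproduce the printed V at two decimals
are flagged exact=False (small denominators amplify rounding).
"""

from __future__ import annotations

from dataclasses import dataclass

from .features import FeatureVector

__all__ = ["VariationRow", "variation_percent", "valsalva_table",
           "VALSALVA_REFERENCE", "TABLE_ORDER"]

#: row order of the comparison table
TABLE_ORDER = [
    "std_enr", "std_enr_h", "std_TM", "std_Ep",
    "TM_max", "TM_min", "enr_max", "enr_min", "enr_h_max", "enr_h_min",
    "Ep_max", "Ep_min",
    "Stotal_50_100", "Stotal_100_150", "Stotal_150_200", "Stotal_200_250",
    "Stotal_250_300", "Stotal_300_350", "Stotal_350_400",
]

#: (feature, Ns, Vm, reported V %, exact) — reference paired measurement;
#: exact=False marks rows whose reported V is not reproducible from the
#: printed Ns/Vm within +-0.06 (rounding of small values)
VALSALVA_REFERENCE = [
    ("std_enr", 12.8, 8.89, 30.71, False),
    ("std_enr_h", 4.99, 3.813, 23.62, True),
    ("std_TM", 19.69, 16.89, 14.23, True),
    ("std_Ep", 7.56, 17.81, -135.53, True),
    ("TM_max", 104.43, 103.25, 1.12, True),
    ("TM_min", 94.55, 96.28, -1.82, True),
    ("enr_max", 91.48, 97.76, -6.87, True),
    ("enr_min", 51.37, 69.55, -35.39, True),
    ("enr_h_max", 14.05, 13.78, 1.88, True),
    ("enr_h_min", 0.37, 0.29, 22.70, False),
    ("Ep_max", 284.13, 142.24, 49.94, True),
    ("Ep_min", 23.92, 23.22, 2.921, True),
    ("Stotal_50_100", 75.02, 87.79, -17.02, True),
    ("Stotal_100_150", 20.86, 8.47, 59.39, True),
    ("Stotal_150_200", 3.56, 1.70, 52.24, True),
    ("Stotal_200_250", 0.46, 0.74, -60.88, True),
    ("Stotal_250_300", 0.063, 0.53, -739.07, False),
    ("Stotal_300_350", 0.017, 0.47, -2647.8, False),
    ("Stotal_350_400", 0.014, 0.29, -1910.61, False),
]


@dataclass
class VariationRow:
    """One feature's normal-state value, maneuver value and percent variation."""

    feature_name: str
    Ns: float
    Vm: float
    V: float

    def __post_init__(self) -> None:
        if self.Ns != 0:
            assert abs(self.V - (self.Ns - self.Vm) / self.Ns * 100.0) < 1e-9


def variation_percent(Ns: float, Vm: float) -> float:
    """Percent variation (Ns - Vm) / Ns * 100 (positive = decreased)."""
    if Ns == 0:
        raise ValueError("variation undefined for Ns = 0")
    return (Ns - Vm) / Ns * 100.0


def valsalva_table(features_ns: FeatureVector,
                   features_vm: FeatureVector) -> list[VariationRow]:
    """Variation rows for the 19 energy features of a paired recording.

    Both vectors must come from the same extraction configuration; a zero
    normal-state entry makes its variation undefined.
    """
    rows = []
    for name in TABLE_ORDER:
        ns = features_ns.values[name]
        vm = features_vm.values[name]
        if ns == 0:
            raise ValueError(f"variation undefined: Ns = 0 for {name}")
        rows.append(VariationRow(feature_name=name, Ns=ns, Vm=vm,
                                 V=variation_percent(ns, vm)))
    return rows
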