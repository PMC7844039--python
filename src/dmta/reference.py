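"""Published reference statistics from the sand tiger shark dietary study.

The dietary-discrimination study of *Carcharias taurus* tooth microwear
that this pipeline re-implements reports a per-parameter ANOVA table (five
samples: the aquarium sample "1", wild specimens "2"-"4" and the
within-tooth repeats "2a") and two pairwise-difference (Tukey HSD) tables.
The values encoded here are the study's printed results; they serve as
inputs for worked examples (the Benjamini–Hochberg step on the published
p-values) and as fixtures for verifying the PCA parameter-selection logic.
They are never produced by this package's own computation.
"""

from __future__ import annotations

__all__ = [
    "ANOVA_TABLE",
    "ANOVA_PVALUES",
    "BH_SIGNIFICANT",
    "PAIRWISE_DIFFERENCES",
    "PCA_SELECTED_PARAMETERS",
    "GROUP_SIZES",
    "DIET_RANKS",
    "PC1_EXPLAINED_PCT",
]

#: Per-parameter ANOVA as published: F statistic, p-value, (df1, df2) and
#: whether the Welch (heteroscedastic) variant was used.  Order is the
#: published row order.
ANOVA_TABLE: dict[str, dict] = {
    "Sq":   {"F": 2.7789,  "p": 0.0781, "df": (4, 11.558), "welch": True},
    "Ssk":  {"F": 2.0122,  "p": 0.1596, "df": (4, 11.457), "welch": True},
    "Sku":  {"F": 5.5796,  "p": 0.0117, "df": (4, 10.413), "welch": True},
    "Sp":   {"F": 1.6849,  "p": 0.1825, "df": (4, 27),     "welch": False},
    "Sv":   {"F": 1.8052,  "p": 0.1926, "df": (4, 12.021), "welch": True},
    "Sz":   {"F": 1.1382,  "p": 0.3873, "df": (4, 11.301), "welch": True},
    "Sds":  {"F": 18.8940, "p": 0.0001, "df": (4, 27),     "welch": False},
    "Str":  {"F": 3.5685,  "p": 0.0393, "df": (4, 11.806), "welch": True},
    "Sal":  {"F": 8.8923,  "p": 0.0001, "df": (4, 27),     "welch": False},
    "Sdq":  {"F": 7.1046,  "p": 0.0037, "df": (4, 11.855), "welch": True},
    "Ssc":  {"F": 3.8799,  "p": 0.0289, "df": (4, 12.433), "welch": True},
    "Sdr":  {"F": 7.3744,  "p": 0.0030, "df": (4, 12.069), "welch": True},
    "Vmp":  {"F": 2.0855,  "p": 0.1505, "df": (4, 11.143), "welch": True},
    "Vmc":  {"F": 2.5595,  "p": 0.0918, "df": (4, 12.24),  "welch": True},
    "Vvc":  {"F": 2.4292,  "p": 0.1042, "df": (4, 12.147), "welch": True},
    "Vvv":  {"F": 3.1651,  "p": 0.0569, "df": (4, 11.334), "welch": True},
    "Spk":  {"F": 1.9043,  "p": 0.1802, "df": (4, 10.958), "welch": True},
    "Sk":   {"F": 2.4630,  "p": 0.1001, "df": (4, 12.334), "welch": True},
    "Svk":  {"F": 3.2954,  "p": 0.0527, "df": (4, 10.96),  "welch": True},
    "Smr1": {"F": 1.7856,  "p": 0.1609, "df": (4, 27),     "welch": False},
    "Smr2": {"F": 4.5516,  "p": 0.0185, "df": (4, 11.841), "welch": True},
    "S5z":  {"F": 1.2853,  "p": 0.3350, "df": (4, 10.774), "welch": True},
    "Sa":   {"F": 2.6142,  "p": 0.0888, "df": (4, 11.902), "welch": True},
}

#: The 23 published ANOVA p-values, in published row order.
ANOVA_PVALUES: dict[str, float] = {k: v["p"] for k, v in ANOVA_TABLE.items()}

#: Parameters the study flags as significant after B–H control at FDR 0.05.
BH_SIGNIFICANT: tuple[str, ...] = ("Sds", "Sal", "Sdq", "Sdr")

#: Published pairwise (Tukey HSD) differences: unordered sample pair ->
#: parameters that differ.  Pairs absent from the mapping showed none.
PAIRWISE_DIFFERENCES: dict[frozenset, tuple[str, ...]] = {
    frozenset({"1", "2"}): ("Sds",),
    frozenset({"1", "3"}): ("Sds", "Sal"),
    frozenset({"1", "4"}): ("Sq", "Sv", "Sz", "Sds", "Sal", "Vmp", "Vmc",
                            "Vvc", "Vvv", "Spk", "Sk", "Svk", "S5z", "Sa"),
    frozenset({"2a", "3"}): ("Sds", "Sal"),
    frozenset({"2a", "4"}): ("Sq", "Sds", "Sal", "Vmp", "Vvv", "Spk",
                             "Svk"),
    frozenset({"2", "4"}): ("Sds",),
}

from .surface_io import ISO_PARAMETER_ORDER as _ORDER  # noqa: E402

#: The 14 parameters with pairwise differences between samples, on which
#: the published PCA is based.  Derived from the encoded pairwise tables
#: (union over pairs) so the constant cannot drift from them.
_sel: set = set()
for _params in PAIRWISE_DIFFERENCES.values():
    _sel.update(_params)
PCA_SELECTED_PARAMETERS: tuple[str, ...] = tuple(
    p for p in _ORDER if p in _sel)

#: Sample sizes of the five ANOVA groups (32 records, classic df (4, 27)).
GROUP_SIZES: dict[str, int] = {"1": 6, "2": 6, "2a": 8, "3": 6, "4": 6}

#: Ordinal diet coding: relative proportion of elasmobranch prey, from the
#: aquarium fish-only sample (1) to the largest wild individual (4).  The
#: within-tooth repeats and the unknown-diet specimen carry no rank.
DIET_RANKS: dict[str, int] = {"1": 1, "2": 2, "3": 3, "4": 4}

#: Published variance captured by PC1 of the correlation-mode PCA.
PC1_EXPLAINED_PCT: float = 83.6
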