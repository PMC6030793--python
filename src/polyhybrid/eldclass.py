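"""Expression-level-dominance (ELD) classification of hybrid genes.

Every coexpressed gene yields a trio of signed differential-expression
calls: hybrid vs maternal parent (d_HA, parent A = BSB), hybrid vs
paternal parent (d_HB, parent B = YB), and parent vs parent (d_AB).
Each sign is -1, 0 or +1 from the dual FDR/fold-change threshold. The
trio is binned into one of twelve categories:

* I, II      — hybrid matches the maternal parent (BSB-ELD)
* III, IV    — hybrid matches the paternal parent (YB-ELD)
* V, VI      — hybrid between unequal parents (additivity / mid-parent)
* VII-IX     — transgressive up (hybrid above both parents)
* X-XII      — transgressive down (hybrid below both parents)

plus NO_CHANGE for (0, 0, 0); the 14 remaining sign triples are
internally inconsistent under the dual-threshold calling (e.g. hybrid
above one parent and below the other while the parents are called equal)
and are reported as AMBIGUOUS rather than silently merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .detest import fisher_exact

#: sign triple (d_HA, d_HB, d_AB) -> roman-numeral category
DECISION_TABLE: dict[tuple[int, int, int], str] = {
    (0, 1, 1): "I",
    (0, -1, -1): "II",
    (1, 0, -1): "III",
    (-1, 0, 1): "IV",
    (-1, 1, 1): "V",
    (1, -1, -1): "VI",
    (1, 1, 1): "VII",
    (1, 1, 0): "VIII",
    (1, 1, -1): "IX",
    (-1, -1, 1): "X",
    (-1, -1, 0): "XI",
    (-1, -1, -1): "XII",
    (0, 0, 0): "NO_CHANGE",
}

#: category -> summary group
CATEGORY_GROUPS: dict[str, str] = {
    "I": "BSB_ELD",
    "II": "BSB_ELD",
    "III": "YB_ELD",
    "IV": "YB_ELD",
    "V": "ADDITIVITY",
    "VI": "ADDITIVITY",
    "VII": "UP",
    "VIII": "UP",
    "IX": "UP",
    "X": "DOWN",
    "XI": "DOWN",
    "XII": "DOWN",
    "NO_CHANGE": "NO_CHANGE",
    "AMBIGUOUS": "AMBIGUOUS",
}

GROUP_LABELS = ("BSB_ELD", "YB_ELD", "ADDITIVITY", "UP", "DOWN", "NO_CHANGE", "AMBIGUOUS")


@dataclass(frozen=True)
class TrioCall:
    """Signed DE calls for one gene: hybrid-vs-BSB, hybrid-vs-YB, BSB-vs-YB."""

    gene_id: str
    d_ha: int
    d_hb: int
    d_ab: int


@dataclass(frozen=True)
class CategoryAssignment:
    gene_id: str
    category: str
    group_label: str


def classify_category(trio: TrioCall) -> CategoryAssignment:
    """Bin one sign trio into its expression category."""
    key = (trio.d_ha, trio.d_hb, trio.d_ab)
    for s in key:
        if s not in (-1, 0, 1):
            raise ValueError(f"sign components must be in {{-1, 0, 1}}, got {key}")
    cat = DECISION_TABLE.get(key, "AMBIGUOUS")
    return CategoryAssignment(trio.gene_id, cat, CATEGORY_GROUPS[cat])


def classify_all(
    calls_vs_a: pd.Series,
    calls_vs_b: pd.Series,
    calls_a_vs_b: pd.Series,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every gene and summarise counts per group label.

    Parameters
    ----------
    calls_vs_a, calls_vs_b, calls_a_vs_b : pandas.Series
        Signed calls indexed by gene id, from the hybrid-vs-BSB,
        hybrid-vs-YB and BSB-vs-YB contrasts (same gene set).

    Returns
    -------
    assignments : DataFrame with d_HA, d_HB, d_AB, category, group_label
    summary : Series of gene counts per group label (all labels present)
    """
    idx = calls_vs_a.index
    for other, name in ((calls_vs_b, "hybrid-vs-YB"), (calls_a_vs_b, "BSB-vs-YB")):
        missing = idx.symmetric_difference(other.index)
        if len(missing):
            raise ValueError(
                f"gene sets differ between contrasts ({name}): "
                f"{list(missing[:5])}{'...' if len(missing) > 5 else ''}"
            )
    d = pd.DataFrame(
        {
            "d_HA": calls_vs_a,
            "d_HB": calls_vs_b.reindex(idx),
            "d_AB": calls_a_vs_b.reindex(idx),
        }
    )
    keys = list(zip(d["d_HA"], d["d_HB"], d["d_AB"]))
    d["category"] = [DECISION_TABLE.get(k, "AMBIGUOUS") for k in keys]
    d["group_label"] = d["category"].map(CATEGORY_GROUPS)
    summary = d["group_label"].value_counts().reindex(GROUP_LABELS, fill_value=0)
    return d, summary


def eld_asymmetry_test(summary_h1: pd.Series, summary_h2: pd.Series) -> pd.DataFrame:
    """Fisher's exact tests for ELD-direction and transgression asymmetry.

    Builds the 2x2 tables (hybrid-1 vs hybrid-2) for the BSB_ELD/YB_ELD
    contrast and the UP/DOWN contrast and returns their two-sided p-values.
    """
    rows = []
    for name, (x, y) in {
        "BSB_ELD_vs_YB_ELD": ("BSB_ELD", "YB_ELD"),
        "UP_vs_DOWN": ("UP", "DOWN"),
    }.items():
        table = [
            [int(summary_h1[x]), int(summary_h1[y])],
            [int(summary_h2[x]), int(summary_h2[y])],
        ]
        rows.append(
            {
                "contrast": name,
                "h1_a": table[0][0],
                "h1_b": table[0][1],
                "h2_a": table[1][0],
                "h2_b": table[1][1],
                "pvalue": fisher_exact(table),
            }
        )
    return pd.DataFrame(rows).set_index("contrast")


def eld_inheritance_overlap(
    assign_2n: pd.DataFrame, assign_3n: pd.DataFrame
) -> dict[str, int]:
    """Overlap of parental-ELD calls between the two hybrids.

    Counts genes that are BSB-ELD in both hybrids, YB-ELD in both,
    parental-ELD in both but toward different parents (discordant), and
    parental-ELD in exactly one hybrid.
    """
    idx = assign_2n.index.union(assign_3n.index)
    g2 = assign_2n["group_label"].reindex(idx)
    g3 = assign_3n["group_label"].reindex(idx)
    eld = {"BSB_ELD", "YB_ELD"}
    is2 = g2.isin(eld)
    is3 = g3.isin(eld)
    both = is2 & is3
    return {
        "shared_BSB_ELD": int((both & (g2 == "BSB_ELD") & (g3 == "BSB_ELD")).sum()),
        "shared_YB_ELD": int((both & (g2 == "YB_ELD") & (g3 == "YB_ELD")).sum()),
        "discordant": int((both & (g2 != g3)).sum()),
        "only_one_hybrid": int((is2 ^ is3).sum()),
    }
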