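"""In-silico mid-parent expression profiles and dosage-compensation calls.

Three synthetic mid-parent profiles (MPVs) model the genome compositions
a hybrid could express, built from the parents' FPKM values chi_BSB and
chi_YB:

* MPV1 = chi_BSB + 1/2 chi_YB   (triploid-like, two maternal doses: BBY)
* MPV2 = 1/2 chi_BSB + 1/2 chi_YB  (diploid mid-parent: BY)
* MPV3 = 1/2 chi_BSB + chi_YB   (triploid-like, two paternal doses: BYY)

Each hybrid's mean FPKM is compared to each profile on the log2 scale
with a fold-change-only threshold (default |log2 ratio| > 1). A triploid
whose expression has been compensated down to the diploid level shows
many more down- than up-calls against MPV1/MPV3 and near-balance against
MPV2 — the signature summarised by :func:`dosage_summary`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detest import fisher_exact
from .quant import FpkmMatrix

#: pseudocount (FPKM) added to both sides of every log2 ratio
EPSILON = 0.1

PROFILES = ("MPV1", "MPV2", "MPV3")
_WEIGHTS = {"MPV1": (1.0, 0.5), "MPV2": (0.5, 0.5), "MPV3": (0.5, 1.0)}


@dataclass
class MpvMatrix:
    """Replicate-level mid-parent FPKM profiles.

    ``values[profile]`` is a genes x replicate-pairs DataFrame; replicate
    pairing is by index within each parent group (recorded in ``pairing``).
    """

    values: dict[str, pd.DataFrame]
    pairing: list[tuple[str, str]]

    def means(self) -> pd.DataFrame:
        """Gene-by-profile matrix of replicate-averaged MPVs."""
        return pd.DataFrame({p: self.values[p].mean(axis=1) for p in PROFILES})


def build_mpv(fpkm: FpkmMatrix) -> MpvMatrix:
    """Construct MPV1/2/3 from the parents' FPKM, paired replicate-wise."""
    bsb = fpkm.samples_of("BSB")
    yb = fpkm.samples_of("YB")
    if len(bsb) != len(yb):
        raise ValueError(
            f"unequal parental replicate counts (BSB {len(bsb)}, YB {len(yb)}): "
            "replicate pairing undefined"
        )
    pairing = list(zip(bsb, yb))
    chi_b = fpkm.values[bsb].to_numpy()
    chi_y = fpkm.values[yb].to_numpy()
    values = {}
    for profile, (wb, wy) in _WEIGHTS.items():
        values[profile] = pd.DataFrame(
            wb * chi_b + wy * chi_y,
            index=fpkm.gene_ids,
            columns=[f"{profile}_{i + 1}" for i in range(len(pairing))],
        )
    return MpvMatrix(values, pairing)


def compare_to_mpv(
    hybrid_fpkm: pd.DataFrame | FpkmMatrix,
    mpv: MpvMatrix,
    lfc_cutoff: float = 1.0,
    hybrid: str | None = None,
) -> pd.DataFrame:
    """Call each gene up/down/unchanged against each MPV profile.

    The statistic is log2(mean hybrid FPKM + eps) - log2(mean MPV + eps);
    calls are +1 above ``lfc_cutoff``, -1 below ``-lfc_cutoff``, else 0.
    Returns a DataFrame with one log2-ratio and one call column per profile.
    """
    if lfc_cutoff <= 0:
        raise ValueError("lfc_cutoff must be positive")
    if isinstance(hybrid_fpkm, FpkmMatrix):
        if hybrid is None:
            raise ValueError("pass hybrid= group label when giving a full FpkmMatrix")
        hybrid_fpkm = hybrid_fpkm.values[hybrid_fpkm.samples_of(hybrid)]
    mpv_means = mpv.means()
    if not hybrid_fpkm.index.equals(mpv_means.index):
        missing = hybrid_fpkm.index.symmetric_difference(mpv_means.index)
        raise ValueError(f"gene sets differ between hybrid and MPV: {list(missing[:5])}")
    h = hybrid_fpkm.mean(axis=1).to_numpy()
    out = pd.DataFrame(index=hybrid_fpkm.index)
    for profile in PROFILES:
        ratio = np.log2(h + EPSILON) - np.log2(mpv_means[profile].to_numpy() + EPSILON)
        call = np.where(ratio > lfc_cutoff, 1, np.where(ratio < -lfc_cutoff, -1, 0))
        out[f"log2_ratio_{profile}"] = ratio
        out[f"call_{profile}"] = call.astype(int)
    return out


def _counts(calls: pd.DataFrame, profile: str) -> tuple[int, int]:
    c = calls[f"call_{profile}"]
    return int((c == 1).sum()), int((c == -1).sum())


def dosage_summary(calls_2n: pd.DataFrame, calls_3n: pd.DataFrame) -> pd.DataFrame:
    """Tabulate up/down calls per hybrid x profile and flag MPV2 bias.

    For each cell the Fisher p-value tests the up-vs-down imbalance of
    that cell against the same hybrid's MPV2 cell. The hybrid-level flag
    ``biased_toward_MPV2`` is set when |up - down| is smallest against
    MPV2 among the three profiles.
    """
    rows = []
    for hybrid, calls in (("2nBY", calls_2n), ("3nBY", calls_3n)):
        n = len(calls)
        ud = {p: _counts(calls, p) for p in PROFILES}
        imbalance = {p: abs(u - d) for p, (u, d) in ud.items()}
        flag = min(imbalance, key=lambda p: (imbalance[p], p)) == "MPV2"
        for p in PROFILES:
            u, d = ud[p]
            u2, d2 = ud["MPV2"]
            if p == "MPV2" or (u + d == 0 and u2 + d2 == 0):
                pval = 1.0
            else:
                pval = fisher_exact([[u, d], [u2, d2]])
            rows.append(
                {
                    "hybrid": hybrid,
                    "profile": p,
                    "up": u,
                    "down": d,
                    "pct_up": 100.0 * u / n if n else 0.0,
                    "pct_down": 100.0 * d / n if n else 0.0,
                    "fisher_p_vs_MPV2": pval,
                    "biased_toward_MPV2": flag,
                }
            )
    return pd.DataFrame(rows).set_index(["hybrid", "profile"])
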