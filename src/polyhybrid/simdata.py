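"""Synthetic parent/hybrid expression and sequence data with known truth.

The generator emulates the statistical structure the analysis assumes:
negative-binomial counts for two parents (BSB maternal, YB paternal) and
two hybrids (allodiploid 2nBY, allotriploid 3nBY) with three replicates
each, a gene mixture over the twelve expression categories plus
no-change genes with a maternal-biased dominance mass, ploidy dosage
scaling of the triploid (compensated to the diploid level, or additive
at 1.5x), and parental transcript sequences diverged by point
substitutions with hybrids copying one parent's allele.

Default parameters are chosen to mirror the study conditions: category
frequencies on the scale of the reported fractions of the 10,057
coexpressed genes (parental dominance ~24%, maternal:paternal ~3:1,
transgressive a few percent, the rest unchanged), log-normal baseline
expression around ~55 counts, and 2.4% parent-parent sequence divergence
(the observed identity scale of the linked orthologs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .eldclass import CATEGORY_GROUPS, DECISION_TABLE
from .orthosim import SequenceSet
from .quant import GROUPS, CountMatrix

CATEGORIES = tuple(
    c for c in CATEGORY_GROUPS if c not in ("AMBIGUOUS",)
)  # I..XII + NO_CHANGE

#: group-mean levels per category, in units of effect_log2fc on the log2
#: scale: (maternal parent A, paternal parent B, hybrid H). Placing each
#: group at level b * 2**(effect * level) realises the category's sign
#: triple with every non-null contrast at or above the effect size.
_CATEGORY_LEVELS: dict[str, tuple[int, int, int]] = {
    "I": (1, 0, 1),
    "II": (0, 1, 0),
    "III": (0, 1, 1),
    "IV": (1, 0, 0),
    "V": (1, -1, 0),
    "VI": (-1, 1, 0),
    "VII": (1, 0, 2),
    "VIII": (0, 0, 1),
    "IX": (0, 1, 2),
    "X": (1, 0, -1),
    "XI": (0, 0, -1),
    "XII": (0, 1, -1),
    "NO_CHANGE": (0, 0, 0),
}

#: default category mixture, on the scale of the reported fractions of
#: coexpressed genes (maternal dominance ~3x the paternal mass)
DEFAULT_CATEGORY_PROBS: dict[str, float] = {
    "I": 0.09,
    "II": 0.09,
    "III": 0.03,
    "IV": 0.03,
    "V": 0.01,
    "VI": 0.01,
    "VII": 0.005,
    "VIII": 0.005,
    "IX": 0.005,
    "X": 0.005,
    "XI": 0.005,
    "XII": 0.005,
    "NO_CHANGE": 0.71,
}


@dataclass
class SimConfig:
    """Parameters of the count simulator.

    Parameters
    ----------
    n_genes : int
        Number of genes.
    n_reps : int
        Replicates per group (default 3, as in the study design).
    category_probs : dict
        Probability per category I..XII plus NO_CHANGE; must sum to 1.
    maternal_bias : float
        Factor >= 1 multiplying the maternal-dominance (categories I, II)
        probability mass before renormalisation.
    baseline_mean_log : (float, float)
        Mean and sd of the natural-log baseline expression level.
    effect_log2fc : float
        True |log2 fold change| of every non-null contrast; must exceed
        the calling threshold of 1.
    nb_dispersion : float or None
        Fixed NB dispersion alpha (variance = mu + alpha mu^2); if None,
        drawn per gene from a log-normal around 0.05.
    triploid_dosage : str
        "compensated" (3nBY mean equals the 2nBY mean) or "additive"
        (1.5x the 2nBY mean).
    gene_length_range : (int, int)
        Effective transcript length interval in bp.
    seed : int
        Random seed; fixing it reproduces counts and truth bit-for-bit.
    """

    n_genes: int
    n_reps: int = 3
    category_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    maternal_bias: float = 1.0
    baseline_mean_log: tuple[float, float] = (4.0, 1.0)
    effect_log2fc: float = 2.0
    nb_dispersion: float | None = None
    dispersion_lognormal: tuple[float, float] = (float(np.log(0.05)), 0.5)
    triploid_dosage: str = "compensated"
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    gene_length_range: tuple[int, int] = (300, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_reps <= 0:
            raise ValueError("n_genes and n_reps must be positive")
        unknown = set(self.category_probs) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        total = sum(self.category_probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"category_probs must sum to 1 (got {total!r})")
        if any(p < 0 for p in self.category_probs.values()):
            raise ValueError("category probabilities must be non-negative")
        if self.maternal_bias < 1.0:
            raise ValueError("maternal_bias must be >= 1")
        if self.effect_log2fc <= 1.0:
            raise ValueError("effect_log2fc must exceed the calling threshold of 1")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.triploid_dosage not in ("compensated", "additive"):
            raise ValueError("triploid_dosage must be 'compensated' or 'additive'")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid gene_length_range")

    def effective_probs(self) -> dict[str, float]:
        """Category probabilities after applying the maternal bias."""
        probs = dict(self.category_probs)
        for c in ("I", "II"):
            probs[c] = probs.get(c, 0.0) * self.maternal_bias
        total = sum(probs.values())
        return {c: p / total for c, p in probs.items()}

    def to_yaml(self, path) -> None:
        data = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in (
            "baseline_mean_log",
            "dispersion_lognormal",
            "size_factor_range",
            "gene_length_range",
        ):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, variance = mu + alpha mu^2) samples; Poisson when alpha ~ 0."""
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    big = ~tiny
    if big.any():
        n = 1.0 / alpha[big]
        p = n / (n + mu[big])
        out[big] = rng.negative_binomial(n, p)
    return out


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a four-group count matrix plus its ground-truth table.

    Returns
    -------
    counts : CountMatrix
        Integer counts, genes x (4 groups x n_reps) samples.
    truth : pandas.DataFrame
        Per gene: true category, true group means (before library-size
        scaling), and length_bp. Classifying the noise-free means with
        the category decision table reproduces the category labels.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    probs = config.effective_probs()
    cats = list(probs)
    labels = rng.choice(cats, size=n, p=[probs[c] for c in cats])

    mu_log, sd_log = config.baseline_mean_log
    baseline = rng.lognormal(mu_log, sd_log, size=n)
    eff = config.effect_log2fc
    levels = np.array([_CATEGORY_LEVELS[c] for c in labels], dtype=float)
    mean_a = baseline * 2.0 ** (eff * levels[:, 0])
    mean_b = baseline * 2.0 ** (eff * levels[:, 1])
    mean_h2 = baseline * 2.0 ** (eff * levels[:, 2])
    dosage = 1.0 if config.triploid_dosage == "compensated" else 1.5
    mean_h3 = mean_h2 * dosage

    if config.nb_dispersion is not None:
        alpha = np.full(n, float(config.nb_dispersion))
    else:
        dm, ds = config.dispersion_lognormal
        alpha = rng.lognormal(dm, ds, size=n)

    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)

    group_means = {"BSB": mean_a, "YB": mean_b, "2nBY": mean_h2, "3nBY": mean_h3}
    sf_lo, sf_hi = config.size_factor_range
    cols, data = [], []
    for group in GROUPS:
        for r in range(config.n_reps):
            sf = rng.uniform(sf_lo, sf_hi)
            cols.append(f"{group}_{r + 1}")
            data.append(_nb_sample(rng, group_means[group] * sf, alpha))

    gene_ids = [f"gene{str(i + 1).zfill(len(str(n)))}" for i in range(n)]
    counts = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
    groups = pd.Series({c: c.rsplit("_", 1)[0] for c in cols})
    truth = pd.DataFrame(
        {
            "category": labels,
            "mean_BSB": mean_a,
            "mean_YB": mean_b,
            "mean_2nBY": mean_h2,
            "mean_3nBY": mean_h3,
            "length_bp": lengths,
        },
        index=gene_ids,
    )
    cm = CountMatrix(counts, truth["length_bp"].astype(float), groups)
    return cm, truth


def classify_noise_free(
    truth: pd.DataFrame, hybrid: str = "2nBY", lfc_cutoff: float = 1.0
) -> pd.Series:
    """Category labels implied by the noise-free true means.

    Applies the threshold rule sign(x, y) = +1 if log2(x/y) > cutoff,
    -1 if < -cutoff, else 0 to the true group means and runs the category
    decision table — an independent consistency check on the generator.
    """

    def sgn(x, y):
        r = np.log2(x / y)
        return np.where(r > lfc_cutoff, 1, np.where(r < -lfc_cutoff, -1, 0))

    h = truth[f"mean_{hybrid}"].to_numpy()
    a = truth["mean_BSB"].to_numpy()
    b = truth["mean_YB"].to_numpy()
    trios = zip(sgn(h, a), sgn(h, b), sgn(a, b))
    cats = [DECISION_TABLE.get(t, "AMBIGUOUS") for t in trios]
    return pd.Series(cats, index=truth.index, name="category")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, rate: float, gc_bias: float = 0.0
) -> np.ndarray:
    """Substitute bases iid at ``rate``; each hit becomes a different base.

    With ``gc_bias`` > 0 the replacement is drawn from {G, C} with that
    probability (if a different base results), else uniformly over the
    three alternatives.
    """
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        if gc_bias > 0 and rng.random() < gc_bias:
            choices = np.array([b for b in (b"G", b"C") if b != out[i]], dtype="S1")
        else:
            choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def simulate_ortholog_sequences(
    n_orthologs: int,
    length_range: tuple[int, int] = (300, 1200),
    divergence: float = 0.024,
    hybrid_source: dict[str, str] | None = None,
    seed: int = 0,
    n_reps: int = 3,
    replicate_divergence: float = 0.002,
    gc_bias_yb: float = 0.0,
    end_extension_max: int = 0,
) -> dict[str, SequenceSet]:
    """Simulate parental and hybrid-replicate transcript sequence sets.

    The maternal (BSB) sequences are random; the paternal (YB) alleles
    derive from them by iid point substitutions at ``divergence`` per
    site (optionally GC-biased). Each hybrid replicate copies its
    configured parent-of-origin allele with ``replicate_divergence``
    extra substitutions, emulating within-group variation. With
    ``end_extension_max`` > 0 random non-collinear bases are appended to
    allele ends, exercising the trimming stage. Returns eight sequence
    sets: BSB, YB, and three replicates per hybrid.
    """
    if not 0 <= divergence < 0.25:
        raise ValueError(
            "divergence must be in [0, 0.25): at >= 25% substitutions the "
            "identity signal saturates toward the random-match floor"
        )
    if hybrid_source is None:
        hybrid_source = {"2nBY": "YB", "3nBY": "BSB"}
    rng = np.random.default_rng(seed)
    lo, hi = length_range

    bsb, yb = {}, {}
    width = len(str(n_orthologs))
    for i in range(n_orthologs):
        oid = f"orth{str(i + 1).zfill(width)}"
        length = int(rng.integers(lo, hi + 1))
        root = rng.choice(_BASES, size=length)
        bsb[oid] = root
        yb[oid] = _mutate(rng, root, divergence, gc_bias=gc_bias_yb)

    parents = {"BSB": bsb, "YB": yb}

    def finalize(arr: np.ndarray) -> str:
        if end_extension_max > 0:
            k5 = int(rng.integers(0, end_extension_max + 1))
            k3 = int(rng.integers(0, end_extension_max + 1))
            arr = np.concatenate(
                [rng.choice(_BASES, size=k5), arr, rng.choice(_BASES, size=k3)]
            )
        return arr.tobytes().decode()

    out: dict[str, SequenceSet] = {}
    for parent, seqs in parents.items():
        out[parent] = SequenceSet(
            {oid: finalize(arr) for oid, arr in seqs.items()}, label=parent
        )
    for hybrid, parent in hybrid_source.items():
        src = parents[parent]
        for r in range(n_reps):
            label = f"{hybrid}_{r + 1}"
            seqs = {
                oid: finalize(_mutate(rng, arr, replicate_divergence))
                for oid, arr in src.items()
            }
            out[label] = SequenceSet(seqs, label=label)
    return out
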