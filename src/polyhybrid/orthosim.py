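"""Ortholog-concatenation sequence analysis.

Expressed ortholog sequences from the parents and each hybrid replicate
are matched one-to-one by reciprocal best hits, trimmed to their
collinear core, and concatenated into one long sequence per sample. The
pairwise identity matrix of these linked sequences, their base
composition, and a neighbor-joining tree on p-distance then show which
parental genome each hybrid's expressed transcripts derive from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

logger = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")
_KMER = 15  # seed length for the alignment candidate prefilter


@dataclass
class SequenceSet:
    """Nucleotide sequences of one sample: identifier -> ACGTN string."""

    sequences: dict[str, str]
    label: str = ""

    def __post_init__(self) -> None:
        clean = {}
        for name, seq in self.sequences.items():
            s = seq.upper()
            if not s:
                raise ValueError(f"empty sequence: {name}")
            extra = set(s) - _ALPHABET
            if extra:
                raise ValueError(f"non-ACGTN characters in {name}: {sorted(extra)}")
            clean[name] = s
        self.sequences = clean

    def __len__(self) -> int:
        return len(self.sequences)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=name, description="")
            for name, s in self.sequences.items()
        ]
        SeqIO.write(records, path, "fasta")

    @classmethod
    def from_fasta(cls, path, label: str = "") -> "SequenceSet":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        return cls(seqs, label=label or str(path))


@dataclass
class LinkedOrthologSet:
    """Concatenated collinear ortholog cores, one equal-length sequence per sample."""

    sequences: dict[str, str]
    segments: list[tuple[str, int, int]] = field(default_factory=list)  # (id, offset, len)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"linked sequences differ in length: {sorted(lengths)}")
        if self.segments:
            offsets = [o for _, o, _ in self.segments]
            if offsets != sorted(offsets) or len(set(offsets)) != len(offsets):
                raise ValueError("segment offsets must be strictly increasing")
            total = sum(n for _, _, n in self.segments)
            if lengths and total != lengths.pop():
                raise ValueError("segment lengths do not sum to the linked length")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def to_fasta(self, path) -> None:
        SequenceSet(self.sequences, label="linked").to_fasta(path)


def _make_aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    if mode == "global":
        # free end gaps: overhangs are trimmed later, not penalised
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    return aligner


def _kmer_index(seqs: dict[str, str]) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for name, s in seqs.items():
        for i in range(0, len(s) - _KMER + 1):
            index.setdefault(s[i : i + _KMER], set()).add(name)
    return index


def _best_hits(
    query: dict[str, str],
    target: dict[str, str],
    aligner: PairwiseAligner,
    min_score: float,
    min_shared_kmers: int = 3,
) -> dict[str, tuple[str, float]]:
    """Best local-alignment hit in ``target`` per query sequence.

    Candidates are prefiltered by shared exact k-mers (seed-and-extend);
    sequences sharing fewer than ``min_shared_kmers`` seeds are never
    aligned, which keeps the all-vs-all search at desk scale.
    """
    index = _kmer_index(target)
    hits: dict[str, tuple[str, float]] = {}
    for qname, qseq in query.items():
        shared: dict[str, int] = {}
        seen = set()
        for i in range(0, len(qseq) - _KMER + 1):
            kmer = qseq[i : i + _KMER]
            if kmer in seen:
                continue
            seen.add(kmer)
            for tname in index.get(kmer, ()):
                shared[tname] = shared.get(tname, 0) + 1
        candidates = [t for t, c in shared.items() if c >= min_shared_kmers]
        best: tuple[str, float] | None = None
        for tname in sorted(candidates):
            score = aligner.score(qseq, target[tname])
            if best is None or score > best[1]:
                best = (tname, score)
        if best is not None and best[1] >= min_score:
            hits[qname] = best
    return hits


def reciprocal_best_hits(
    set_a: SequenceSet,
    set_b: SequenceSet,
    min_len: int = 200,
    min_score: float = 100.0,
) -> list[tuple[str, str]]:
    """One-to-one ortholog pairs between two samples.

    Sequences shorter than ``min_len`` bp are dropped; each remaining
    sequence is locally aligned (match +1, mismatch -1, gap open -5, gap
    extend -2) against its k-mer-sharing candidates in the other set, and
    a pair (a, b) is kept iff each is the other's best hit with an
    alignment score of at least ``min_score``.
    """
    a = {n: s for n, s in set_a.sequences.items() if len(s) >= min_len}
    b = {n: s for n, s in set_b.sequences.items() if len(s) >= min_len}
    if not a or not b:
        raise ValueError(f"no sequences >= {min_len} bp in one of the sets")
    aligner = _make_aligner("local")
    ab = _best_hits(a, b, aligner, min_score)
    ba = _best_hits(b, a, aligner, min_score)
    pairs = [
        (qa, hit)
        for qa, (hit, _) in sorted(ab.items())
        if ba.get(hit, (None,))[0] == qa
    ]
    logger.info("reciprocal best hits: %d pairs from %d x %d sequences", len(pairs), len(a), len(b))
    return pairs


def find_shared_orthologs(
    seq_sets: dict[str, SequenceSet],
    anchor: str = "BSB",
    min_len: int = 200,
    min_score: float = 100.0,
) -> dict[str, dict[str, str]]:
    """Ortholog alleles present in every sample, keyed by anchor-sample id.

    Runs reciprocal best hits between the anchor sample and every other
    sample; an ortholog is retained only if it has an RBH partner in all
    samples. Returns ortholog id -> {sample label -> allele sequence}.
    """
    if anchor not in seq_sets:
        raise KeyError(f"anchor sample {anchor!r} not among {sorted(seq_sets)}")
    anchor_set = seq_sets[anchor]
    alleles: dict[str, dict[str, str]] = {
        name: {anchor: seq}
        for name, seq in anchor_set.sequences.items()
        if len(seq) >= min_len
    }
    for label, sset in seq_sets.items():
        if label == anchor:
            continue
        pairs = reciprocal_best_hits(anchor_set, sset, min_len=min_len, min_score=min_score)
        for a_id, b_id in pairs:
            if a_id in alleles:
                alleles[a_id][label] = sset.sequences[b_id]
    n_samples = len(seq_sets)
    shared = {k: v for k, v in alleles.items() if len(v) == n_samples}
    for k in sorted(set(alleles) - set(shared)):
        logger.info("ortholog %s dropped: present in %d/%d samples", k, len(alleles[k]), n_samples)
    return shared


def _project_onto_reference(ref: str, seq: str, aligner: PairwiseAligner) -> str:
    """Allele written in reference coordinates; uncovered positions become '-'."""
    aln = aligner.align(ref, seq)[0]
    out = ["-"] * len(ref)
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            out[t0 + k] = seq[q0 + k]
    return "".join(out)


def trim_and_link(
    alleles: dict[str, dict[str, str]],
    sample_order: list[str],
    min_core: int = 100,
) -> LinkedOrthologSet:
    """Trim each ortholog to its collinear core and concatenate per sample.

    Every allele is globally aligned (free end gaps) to the first sample's
    allele and projected onto its coordinates; terminal columns where any
    sample shows an end gap are trimmed from both ends, interior gaps
    become 'N', orthologs whose trimmed core is shorter than ``min_core``
    bp are dropped, and the survivors are concatenated in lexicographic
    ortholog-id order.
    """
    aligner = _make_aligner("global")
    parts: dict[str, list[str]] = {s: [] for s in sample_order}
    segments: list[tuple[str, int, int]] = []
    offset = 0
    for oid in sorted(alleles):
        per_sample = alleles[oid]
        missing = [s for s in sample_order if s not in per_sample]
        if missing:
            logger.info("ortholog %s dropped: missing in %s", oid, missing)
            continue
        ref = per_sample[sample_order[0]]
        rows = [ref] + [
            _project_onto_reference(ref, per_sample[s], aligner)
            for s in sample_order[1:]
        ]
        lead = max(len(r) - len(r.lstrip("-")) for r in rows)
        trail = max(len(r) - len(r.rstrip("-")) for r in rows)
        hi = len(ref) - trail
        if hi - lead < min_core:
            logger.info("ortholog %s dropped: trimmed core %d bp < %d", oid, max(hi - lead, 0), min_core)
            continue
        for sample, row in zip(sample_order, rows):
            parts[sample].append(row[lead:hi].replace("-", "N"))
        segments.append((oid, offset, hi - lead))
        offset += hi - lead
    if not segments:
        raise ValueError("no ortholog survived trimming")
    return LinkedOrthologSet(
        {s: "".join(chunks) for s, chunks in parts.items()}, segments
    )


def identity_matrix(linked: LinkedOrthologSet) -> pd.DataFrame:
    """Pairwise identity over positions where both sequences are non-N."""
    labels = list(linked.sequences)
    if len(labels) < 2:
        raise ValueError("need at least two samples")
    arrs = {s: np.frombuffer(seq.encode(), dtype="S1") for s, seq in linked.sequences.items()}
    n_char = np.bytes_(b"N")
    mat = np.eye(len(labels))
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            ok = (arrs[a] != n_char) & (arrs[b] != n_char)
            total = int(ok.sum())
            if total == 0:
                raise ValueError(f"no comparable (non-N) positions between {a} and {b}")
            ident = float((arrs[a][ok] == arrs[b][ok]).sum()) / total
            mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=labels, columns=labels)


def base_composition(linked: LinkedOrthologSet) -> pd.DataFrame:
    """Per-sample A+T and G+C percentages over non-N positions."""
    rows = {}
    for sample, seq in linked.sequences.items():
        counts = {b: seq.count(b) for b in "ACGT"}
        total = sum(counts.values())
        at = 100.0 * (counts["A"] + counts["T"]) / total if total else float("nan")
        rows[sample] = {"AT_pct": at, "GC_pct": 100.0 - at if total else float("nan")}
    return pd.DataFrame.from_dict(rows, orient="index")


def nj_tree(identity: pd.DataFrame) -> str:
    """Neighbor-joining Newick tree on p-distance d = 1 - identity.

    Negative branch lengths are clamped to zero; tie-breaking follows the
    input sample order, so the output is deterministic.
    """
    if identity.shape[0] < 3:
        raise ValueError("need at least three samples for a tree")
    dist = 1.0 - identity.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    dm = DistanceMatrix(dist, ids=list(identity.index))
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
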