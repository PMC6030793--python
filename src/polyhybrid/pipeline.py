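"""End-to-end orchestration of the duplicated-gene expression analysis.

``run_all`` sequences the stages — FPKM quantification and coexpression
filtering, pairwise differential expression (each hybrid vs each parent
and parent vs parent), twelve-category dominance classification for both
hybrids, mid-parent dosage comparison, and (when sequences are supplied
or simulated) the ortholog-concatenation similarity analysis — writing a
TSV per stage, a plain-text report, and a machine-readable JSON summary
validated against the shipped schema model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel

from . import detest, dosage, eldclass, orthosim, quant, simdata

logger = logging.getLogger(__name__)

ALL_STAGES = ("quant", "detest", "eld", "dosage", "ortho")

#: differential-expression contrasts, group A first (log2FC is A vs B)
CONTRASTS = (
    ("2nBY", "BSB"),
    ("2nBY", "YB"),
    ("3nBY", "BSB"),
    ("3nBY", "YB"),
    ("BSB", "YB"),
)


def pct(count: int, total: int) -> float:
    """Count as a percentage of the coexpressed total, 2 decimals."""
    return round(100.0 * count / total, 2) if total else 0.0


class ContrastSummary(BaseModel):
    group_a: str
    group_b: str
    n_deg: int
    n_up: int
    n_down: int
    pct_deg: float
    pct_up: float
    pct_down: float


class EldSummary(BaseModel):
    hybrid: str
    counts: dict[str, int]
    percentages: dict[str, float]


class DosageCell(BaseModel):
    hybrid: str
    profile: str
    up: int
    down: int
    pct_up: float
    pct_down: float
    fisher_p_vs_MPV2: float
    biased_toward_MPV2: bool


class ReportSummary(BaseModel):
    """Schema of the machine-readable run summary."""

    seed: int
    n_genes_input: int
    n_coexpressed: int
    contrasts: list[ContrastSummary] = []
    eld: list[EldSummary] = []
    eld_asymmetry_p: dict[str, float] = {}
    eld_inheritance: dict[str, int] = {}
    dosage: list[DosageCell] = []
    identity_matrix: dict[str, dict[str, float]] = {}
    base_composition: dict[str, dict[str, float]] = {}
    nj_tree_newick: str = ""
    stages_run: list[str] = []


@dataclass
class RunConfig:
    """Paths, cutoffs and stage toggles for one full run."""

    out_dir: str
    counts_tsv: str | None = None
    fasta_dir: str | None = None
    sim: simdata.SimConfig | None = None
    sim_orthologs: dict | None = None  # kwargs for simulate_ortholog_sequences
    deg_fdr: float = 0.001
    category_fdr: float = 0.005
    lfc: float = 1.0
    mpv_lfc: float = 1.0
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        for cut in (self.deg_fdr, self.category_fdr, self.lfc, self.mpv_lfc):
            if cut <= 0:
                raise ValueError("all cutoffs must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _resign(frame: pd.DataFrame, fdr_cutoff: float, lfc_cutoff: float) -> pd.Series:
    """Re-threshold a fitted contrast at different cutoffs."""
    import numpy as np

    hit = (frame["fdr"] < fdr_cutoff) & (frame["log2fc"].abs() > lfc_cutoff)
    return pd.Series(
        np.where(hit, np.sign(frame["log2fc"]), 0).astype(int), index=frame.index
    )


def run_all(config: RunConfig) -> ReportSummary:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_lines: list[str] = [f"polyhybrid run (seed {config.seed})", ""]
    summary = ReportSummary(seed=config.seed, n_genes_input=0, n_coexpressed=0)

    if not config.stages:
        summary_path = out / "summary.json"
        summary_path.write_text(summary.model_dump_json(indent=2))
        (out / "report.txt").write_text("\n".join(report_lines) + "\n")
        return summary

    stage = "init"
    try:
        # ---- counts in ------------------------------------------------
        stage = "quant"
        if config.counts_tsv is not None:
            counts = quant.CountMatrix.from_tsv(config.counts_tsv)
            truth = None
        else:
            sim = config.sim or simdata.SimConfig(n_genes=2000, seed=config.seed)
            counts, truth = simdata.simulate_counts(sim)
            counts.to_tsv(out / "simulated_counts.tsv")
            truth.to_csv(out / "simulated_truth.tsv", sep="\t", index_label="gene_id")
        summary.n_genes_input = len(counts.gene_ids)

        fpkm = quant.compute_fpkm(counts)
        fpkm_f, counts_f = quant.filter_coexpressed(fpkm, counts)
        n_co = len(fpkm_f.gene_ids)
        summary.n_coexpressed = n_co
        summary.stages_run.append("quant")
        fpkm_f.to_tsv(out / "fpkm_coexpressed.tsv")
        report_lines += [
            f"coexpression filter: {n_co} of {summary.n_genes_input} genes retained "
            f"({pct(n_co, summary.n_genes_input):.2f}%)",
            "",
        ]

        # ---- differential expression ----------------------------------
        fits: dict[tuple[str, str], detest.NBDiffExpressionResults] = {}
        if "detest" in config.stages:
            stage = "detest"
            for a, b in CONTRASTS:
                res = detest.nb_test(
                    counts_f, a, b, fdr_cutoff=config.deg_fdr, lfc_cutoff=config.lfc
                )
                fits[(a, b)] = res
                res.to_tsv(out / f"detest_{a}_vs_{b}.tsv")
                n_up, n_down = res.n_up(), res.n_down()
                n_deg = n_up + n_down
                summary.contrasts.append(
                    ContrastSummary(
                        group_a=a, group_b=b, n_deg=n_deg, n_up=n_up, n_down=n_down,
                        pct_deg=pct(n_deg, n_co), pct_up=pct(n_up, n_co),
                        pct_down=pct(n_down, n_co),
                    )
                )
                report_lines.append(
                    f"DEGs {a} vs {b}: {n_deg} ({pct(n_deg, n_co):.2f}%) — "
                    f"{n_up} up ({pct(n_up, n_co):.2f}%), "
                    f"{n_down} down ({pct(n_down, n_co):.2f}%)"
                )
            report_lines.append("")
            summary.stages_run.append("detest")

        # ---- twelve-category dominance classification ------------------
        assignments: dict[str, pd.DataFrame] = {}
        if "eld" in config.stages:
            stage = "eld"
            if not fits:
                raise RuntimeError("eld stage requires the detest stage")
            summaries = {}
            for hybrid in ("2nBY", "3nBY"):
                signs = {
                    key: _resign(fits[key].frame, config.category_fdr, config.lfc)
                    for key in ((hybrid, "BSB"), (hybrid, "YB"), ("BSB", "YB"))
                }
                assign, s = eldclass.classify_all(
                    signs[(hybrid, "BSB")], signs[(hybrid, "YB")], signs[("BSB", "YB")]
                )
                assignments[hybrid] = assign
                summaries[hybrid] = s
                assign.to_csv(out / f"eld_{hybrid}.tsv", sep="\t", index_label="gene_id")
                summary.eld.append(
                    EldSummary(
                        hybrid=hybrid,
                        counts={k: int(v) for k, v in s.items()},
                        percentages={k: pct(int(v), n_co) for k, v in s.items()},
                    )
                )
                report_lines.append(
                    f"ELD {hybrid}: "
                    + ", ".join(
                        f"{k}={int(v)} ({pct(int(v), n_co):.2f}%)" for k, v in s.items()
                    )
                )
            asym = eldclass.eld_asymmetry_test(summaries["2nBY"], summaries["3nBY"])
            asym.to_csv(out / "eld_asymmetry.tsv", sep="\t")
            summary.eld_asymmetry_p = {
                str(k): float(v) for k, v in asym["pvalue"].items()
            }
            summary.eld_inheritance = eldclass.eld_inheritance_overlap(
                assignments["2nBY"], assignments["3nBY"]
            )
            report_lines += [
                "ELD asymmetry Fisher p: "
                + ", ".join(f"{k}={v:.3g}" for k, v in summary.eld_asymmetry_p.items()),
                f"ELD inheritance overlap: {summary.eld_inheritance}",
                "",
            ]
            summary.stages_run.append("eld")

        # ---- mid-parent dosage comparison ------------------------------
        if "dosage" in config.stages:
            stage = "dosage"
            mpv = dosage.build_mpv(fpkm_f)
            calls = {
                h: dosage.compare_to_mpv(fpkm_f, mpv, lfc_cutoff=config.mpv_lfc, hybrid=h)
                for h in ("2nBY", "3nBY")
            }
            for h, c in calls.items():
                c.to_csv(out / f"dosage_calls_{h}.tsv", sep="\t", index_label="gene_id",
                         float_format="%.6g")
            dsum = dosage.dosage_summary(calls["2nBY"], calls["3nBY"])
            dsum.to_csv(out / "dosage_summary.tsv", sep="\t", float_format="%.6g")
            for (h, profile), row in dsum.iterrows():
                summary.dosage.append(
                    DosageCell(
                        hybrid=h, profile=profile, up=int(row["up"]),
                        down=int(row["down"]),
                        pct_up=pct(int(row["up"]), n_co),
                        pct_down=pct(int(row["down"]), n_co),
                        fisher_p_vs_MPV2=float(row["fisher_p_vs_MPV2"]),
                        biased_toward_MPV2=bool(row["biased_toward_MPV2"]),
                    )
                )
                report_lines.append(
                    f"dosage {h} vs {profile}: up={int(row['up'])} "
                    f"({pct(int(row['up']), n_co):.2f}%), down={int(row['down'])} "
                    f"({pct(int(row['down']), n_co):.2f}%)"
                )
            report_lines.append("")
            summary.stages_run.append("dosage")

        # ---- ortholog concatenation ------------------------------------
        if "ortho" in config.stages:
            stage = "ortho"
            if config.fasta_dir is not None:
                seq_sets = {
                    p.stem: orthosim.SequenceSet.from_fasta(p, label=p.stem)
                    for p in sorted(Path(config.fasta_dir).glob("*.fa*"))
                }
            else:
                kwargs = dict(config.sim_orthologs or {"n_orthologs": 60})
                kwargs.setdefault("seed", config.seed)
                seq_sets = simdata.simulate_ortholog_sequences(**kwargs)
            if len(seq_sets) >= 3:
                alleles = orthosim.find_shared_orthologs(seq_sets)
                order = list(seq_sets)
                linked = orthosim.trim_and_link(alleles, order)
                linked.to_fasta(out / "linked_orthologs.fasta")
                ident = orthosim.identity_matrix(linked)
                ident.to_csv(out / "identity_matrix.tsv", sep="\t", float_format="%.4f")
                comp = orthosim.base_composition(linked)
                comp.to_csv(out / "base_composition.tsv", sep="\t", float_format="%.3f")
                tree = orthosim.nj_tree(ident)
                (out / "nj_tree.nwk").write_text(tree + "\n")
                summary.identity_matrix = {
                    a: {b: round(float(v), 4) for b, v in row.items()}
                    for a, row in ident.iterrows()
                }
                summary.base_composition = {
                    s: {k: round(float(v), 3) for k, v in row.items()}
                    for s, row in comp.iterrows()
                }
                summary.nj_tree_newick = tree
                report_lines += [
                    f"linked orthologs: {len(linked.segments)} segments, "
                    f"{linked.length} bp per sample",
                    "identity matrix written to identity_matrix.tsv",
                    "",
                ]
                summary.stages_run.append("ortho")
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err

    (out / "summary.json").write_text(summary.model_dump_json(indent=2))
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    return summary


def report_json_schema() -> dict:
    """The JSON schema the run summary validates against."""
    return ReportSummary.model_json_schema()


def validate_summary(path) -> ReportSummary:
    """Load and validate a summary.json produced by :func:`run_all`."""
    return ReportSummary.model_validate(json.loads(Path(path).read_text()))
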