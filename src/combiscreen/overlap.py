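"""Direction-matched overlap of DEG lists with prognostic risk classes.

Candidate targets are genes whose expression change under treatment points
against their prognostic direction in patients: up-regulated genes that are
low-risk (protective) in the survival screen, and down-regulated genes that
are high-risk. This module also hosts the end-to-end pipeline runner
(simulate -> differential expression -> survival screen -> overlap ->
report) used by the ``run-all`` command.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, io, simdata, survscreen

__all__ = [
    "GeneSet",
    "OverlapResult",
    "direction_matched_overlap",
    "write_report",
    "PipelineConfig",
    "run_pipeline",
]


def _normalize(genes) -> frozenset:
    # exact-string matching after case normalization; no alias resolution
    return frozenset(str(g).strip().upper() for g in genes)


@dataclass(frozen=True)
class GeneSet:
    label: str
    genes: frozenset

    @classmethod
    def from_iterable(cls, label: str, genes) -> "GeneSet":
        return cls(label=label, genes=_normalize(genes))

    def __len__(self) -> int:
        return len(self.genes)

    def sorted(self) -> list[str]:
        return sorted(self.genes)


@dataclass(frozen=True)
class OverlapResult:
    up_low_risk: GeneSet
    down_high_risk: GeneSet
    candidate_targets: GeneSet

    def counts(self) -> dict:
        return {
            "up_low_risk": len(self.up_low_risk),
            "down_high_risk": len(self.down_high_risk),
            "candidate_targets": len(self.candidate_targets),
        }


def direction_matched_overlap(up, down, low_risk, high_risk) -> OverlapResult:
    """Intersect DEG lists with prognostic classes, direction-matched.

    up_low_risk = up ∩ low_risk; down_high_risk = down ∩ high_risk;
    candidate_targets is their union. Gene ids are matched exactly after
    case normalization. A gene appearing in both the up and down inputs
    marks inconsistent upstream output and is rejected.
    """
    up, down = _normalize(up), _normalize(down)
    low_risk, high_risk = _normalize(low_risk), _normalize(high_risk)
    both = up & down
    if both:
        raise ValueError(
            f"inconsistent DEG input: gene(s) listed as both up and down: {sorted(both)[:5]}"
        )
    up_low = GeneSet("up_low_risk", up & low_risk)
    down_high = GeneSet("down_high_risk", down & high_risk)
    return OverlapResult(
        up_low_risk=up_low,
        down_high_risk=down_high,
        candidate_targets=GeneSet("candidate_targets", up_low.genes | down_high.genes),
    )


def write_report(
    outdir,
    overlap: OverlapResult,
    *,
    deg: pd.DataFrame | None = None,
    screen: pd.DataFrame | None = None,
) -> dict:
    """Write the machine-readable and plain-text overlap report.

    Emits ``up_low_risk.txt``, ``down_high_risk.txt``,
    ``candidate_targets.txt``, ``summary.json`` and ``summary.txt`` under
    ``outdir``. When the per-gene DEG and screen tables are supplied, the
    JSON carries per-candidate provenance (logFC, fdr, hr, gap_5yr). Output
    ordering is alphabetical by gene, so reruns on identical inputs are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    io.write_gene_list(overlap.up_low_risk.sorted(), outdir / "up_low_risk.txt")
    io.write_gene_list(overlap.down_high_risk.sorted(), outdir / "down_high_risk.txt")
    io.write_gene_list(overlap.candidate_targets.sorted(), outdir / "candidate_targets.txt")

    provenance = {}
    for gene in overlap.candidate_targets.sorted():
        entry = {}
        if deg is not None and gene in deg.index:
            entry["logFC"] = float(deg.loc[gene, "logFC"])
            entry["fdr"] = float(deg.loc[gene, "fdr"])
        if screen is not None and gene in screen.index:
            entry["hr"] = float(screen.loc[gene, "hr"])
            entry["gap_5yr"] = float(screen.loc[gene, "gap_5yr"])
        provenance[gene] = entry

    summary = {
        "counts": overlap.counts(),
        "up_low_risk": overlap.up_low_risk.sorted(),
        "down_high_risk": overlap.down_high_risk.sorted(),
        "candidate_targets": overlap.candidate_targets.sorted(),
        "provenance": provenance,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    lines = ["candidate-target overlap summary", ""]
    for key, count in sorted(overlap.counts().items()):
        lines.append(f"{key}: {count}")
    lines.append("")
    lines.append("candidate targets:")
    lines += [f"  {g}" for g in overlap.candidate_targets.sorted()] or ["  (none)"]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return summary


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass(frozen=True)
class PipelineConfig:
    """Stated world of one end-to-end synthetic run.

    The gene universe holds ``n_genes`` genes; the first blocks are planted:
    ``n_up_protective`` genes up-regulated by treatment and protective in
    the cohort (the classic candidate-target pattern), ``n_down_hazardous``
    down-regulated and hazardous, ``n_mismatched`` genes whose DE and
    prognostic directions disagree (alternating up+hazardous /
    down+protective — these must never be nominated), and ``n_de_only``
    extra DE genes with no survival effect. The prognostic planting is kept
    sparse (~1.5% of genes) because every planted gene feeds one joint
    proportional-hazards model: dense planting acts as frailty and
    attenuates each gene's marginal effect.
    """

    n_genes: int = 500
    n_up_protective: int = 3
    n_down_hazardous: int = 3
    n_mismatched: int = 2
    n_de_only: int = 24
    # count-matrix world
    n_per_group: int = 5
    lib_size: float = 1_000_000.0
    dispersion: float = 0.05
    lfc_magnitude: float = 4.0
    # cohort world
    n_samples: int = 400
    beta: float = math.log(3.0)
    baseline_hazard: float = math.log(2.0) / 1825.0
    censor_rate: float = 1e-4
    horizon: float = 3650.0
    # filters
    lfc_cut: float = 2.0
    fdr_cut: float = 0.05
    criteria: survscreen.ScreenCriteria = field(default_factory=survscreen.ScreenCriteria)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        crit = raw.pop("criteria", None)
        if crit is not None:
            raw["criteria"] = survscreen.ScreenCriteria(**crit)
        return cls(**raw)

    def planted(self):
        """(de_index, de_sign, prog_index, prog_sign, truth frame)."""
        nup, ndown, nmis, nde = (
            self.n_up_protective, self.n_down_hazardous, self.n_mismatched, self.n_de_only,
        )
        total = nup + ndown + nmis + nde
        if total > self.n_genes:
            raise ValueError("planted genes exceed the gene universe")
        genes = [f"G{i:04d}" for i in range(self.n_genes)]
        rows = []
        for i in range(nup):
            rows.append((i, +1.0, -1.0, "consistent"))
        for i in range(nup, nup + ndown):
            rows.append((i, -1.0, +1.0, "consistent"))
        for j, i in enumerate(range(nup + ndown, nup + ndown + nmis)):
            # alternate up+hazardous / down+protective
            s = +1.0 if j % 2 == 0 else -1.0
            rows.append((i, s, s, "mismatched"))
        for j, i in enumerate(range(nup + ndown + nmis, total)):
            rows.append((i, +1.0 if j % 2 == 0 else -1.0, 0.0, "de_only"))
        truth = pd.DataFrame(rows, columns=["idx", "de_sign", "prog_sign", "kind"])
        truth["gene"] = [genes[i] for i in truth["idx"]]
        de = truth[truth["de_sign"] != 0]
        prog = truth[truth["prog_sign"] != 0]
        return (
            de["idx"].to_numpy(), de["de_sign"].to_numpy(),
            prog["idx"].to_numpy(), prog["prog_sign"].to_numpy(),
            truth.set_index("gene"),
        )


def run_pipeline(config: PipelineConfig, seed: int = 0, outdir=None) -> dict:
    """Run simulate -> DEG -> survival screen -> overlap on one seed.

    Per-stage seeds are derived deterministically from the global seed.
    Returns a dict with the stage tables, the overlap result and the planted
    truth; when ``outdir`` is given, all stage outputs and the report are
    written beneath it.
    """
    stage_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, 2)
    de_idx, de_sign, prog_idx, prog_sign, truth = config.planted()

    count_spec = simdata.CountSimSpec(
        n_genes=config.n_genes, n_per_group=config.n_per_group,
        lib_size=config.lib_size, dispersion=config.dispersion,
        frac_de=0.0, lfc_magnitude=config.lfc_magnitude, seed=int(stage_seeds[0]),
    )
    counts, groups, _ = simdata.simulate_counts(count_spec, de_index=de_idx, de_sign=de_sign)

    surv_spec = simdata.SurvivalSimSpec(
        n_samples=config.n_samples, n_genes=config.n_genes,
        frac_prognostic=0.0, beta=config.beta,
        baseline_hazard=config.baseline_hazard, censor_rate=config.censor_rate,
        horizon=config.horizon, seed=int(stage_seeds[1]),
    )
    expr, surv, _ = simdata.simulate_survival_cohort(
        surv_spec, prognostic_index=prog_idx, prognostic_sign=prog_sign,
    )

    deg = diffexpr.deg_table(counts, groups, config.lfc_cut, config.fdr_cut)
    up, down = diffexpr.call_degs(deg, config.lfc_cut, config.fdr_cut)

    screen = survscreen.screen_genes(expr, surv, config.criteria)
    high_risk, low_risk = survscreen.risk_gene_lists(screen)

    overlap = direction_matched_overlap(up, down, low_risk, high_risk)

    result = {
        "counts": counts, "groups": groups, "expr": expr, "surv": surv,
        "deg": deg, "up": up, "down": down,
        "screen": screen, "high_risk": high_risk, "low_risk": low_risk,
        "overlap": overlap, "truth": truth,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_matrix(counts, outdir / "counts.tsv")
        io.write_groups(groups, outdir / "groups.tsv")
        io.write_matrix(expr, outdir / "expr.tsv")
        io.write_survival(surv, outdir / "surv.tsv")
        deg.to_csv(outdir / "deg.tsv", sep="\t", index_label="gene")
        screen.to_csv(outdir / "screen.tsv", sep="\t", index_label="gene")
        io.write_gene_list(up, outdir / "up.txt")
        io.write_gene_list(down, outdir / "down.txt")
        io.write_gene_list(high_risk, outdir / "high_risk.txt")
        io.write_gene_list(low_risk, outdir / "low_risk.txt")
        write_report(outdir, overlap, deg=deg, screen=screen)
    return result
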