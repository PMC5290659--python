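"""End-to-end pipeline: mining -> duplication -> Ka/Ks -> clock -> motif -> tree.

The orchestrator runs every stage over either a FASTA/TSV input set or a
simulated family, writes all tabular/FASTA/newick outputs plus a
run-metadata record, and returns the in-memory report bundle. Stage
failures are re-raised with the stage name attached.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import yaml

from . import io as ugio
from .align import global_align, project_to_codons
from .clock import DEFAULT_RATE, DivergenceEstimate, time_matrix_rows
from .duplication import (
    calibrate_score_threshold,
    classify_pairs,
    reciprocal_best_hits,
)
from .kaks import classify_results, compute_kaks, filter_pairs
from .motif import build_profile, scan_pspg
from .phylogeny import bootstrap, nj_tree, p_distance
from .sequence import CodingGene, length_filter
from .simulate import SimConfig, simulate_family
from .summary import DEFAULT_BIN_WIDTH, ks_summary

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@contextlib.contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; YAML-loadable."""

    outdir: str = "results/pipeline"
    # input: either a simulation config or FASTA/TSV paths
    simulation: SimConfig | None = None
    cds_fasta: str | None = None
    chromosome_table: str | None = None
    # stage parameters
    min_fraction: float = 0.5
    score_threshold: float | None = None  # None -> permutation calibration
    rate_r: float = DEFAULT_RATE
    neutral_band: float = 0.0
    motif_seeds: list[str] = field(default_factory=list)
    motif_flank: int = 50
    bootstrap_reps: int = 100
    bin_width: float = DEFAULT_BIN_WIDTH
    seed: int = 0


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline configuration from YAML."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        if "motif" in sim and sim["motif"] is not None:
            sim["motif"] = tuple(sim["motif"])
        cfg.simulation = SimConfig(**sim)
    return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"outdir": str(outdir)}

    # -- input / simulate -------------------------------------------------
    truth = None
    with _stage("input"):
        if config.simulation is not None:
            genes, truth = simulate_family(config.simulation)
            ugio.write_fasta(outdir / "genes_cds.fasta", {g.id: g.cds for g in genes})
            ugio.write_tsv(
                outdir / "truth.tsv",
                [asdict(p) for p in truth.pairs],
                ["id_a", "id_b", "true_t_mya", "true_expected_ks", "true_omega"],
            )
        elif config.cds_fasta:
            genes = ugio.read_coding_genes(config.cds_fasta, config.chromosome_table)
        else:
            raise ValueError("config needs either a simulation block or cds_fasta")

    # -- mining: length filter --------------------------------------------
    with _stage("mining"):
        if not genes:
            raise ValueError("empty gene set")
        proteins = [g.protein_record() for g in genes]
        kept_prot, excluded = length_filter(proteins, config.min_fraction)
        kept_ids = {p.id for p in kept_prot}
        genes = [g for g in genes if g.id in kept_ids]
        report["mining"] = {"n_kept": len(kept_prot), "n_excluded": len(excluded)}
        ugio.write_fasta(outdir / "proteins.fasta", {p.id: p.sequence for p in kept_prot})

    # -- pairwise alignment + scores --------------------------------------
    with _stage("alignment"):
        if len(genes) < 2:
            raise ValueError("need at least 2 genes after mining")
        by_id = {g.id: g for g in genes}
        alignments = {}
        for ga, gb in combinations(genes, 2):
            key = tuple(sorted((ga.id, gb.id)))
            a, b = by_id[key[0]], by_id[key[1]]
            alignments[key] = global_align(a.protein, b.protein, key[0], key[1])
        scores = {k: a.score for k, a in alignments.items()}
        ugio.write_tsv(
            outdir / "scores.tsv",
            [{"id_a": a, "id_b": b, "score": s} for (a, b), s in sorted(scores.items())],
            ["id_a", "id_b", "score"],
        )

    # -- duplication: threshold, RBH, census -------------------------------
    with _stage("duplication"):
        threshold = config.score_threshold
        if threshold is None:
            threshold = calibrate_score_threshold(
                {g.id: g.protein for g in genes}, seed=config.seed
            )
        passing = {k: s for k, s in scores.items() if s >= threshold}
        rbh = reciprocal_best_hits(passing)
        chrom_map = {g.id: g.chromosome for g in genes if g.chromosome}
        rbh, census = classify_pairs(rbh, chrom_map, n_genes_total=len(genes))
        report["duplication"] = {"score_threshold": threshold, "census": census}
        ugio.write_tsv(
            outdir / "duplication_pairs.tsv",
            [asdict(p) for p in rbh],
            ["id_a", "id_b", "score", "chromosome_a", "chromosome_b", "kind"],
        )

    # -- Ka/Ks over all aligned pairs --------------------------------------
    with _stage("kaks"):
        results = []
        for (ia, ib), aln in sorted(alignments.items()):
            codons = project_to_codons(aln, by_id[ia].cds, by_id[ib].cds)
            results.append(compute_kaks(codons))
        filter_pairs(results)
        classify_results(results, config.neutral_band)

    # -- clock dating -------------------------------------------------------
    with _stage("clock"):
        estimates = [
            DivergenceEstimate(r.id_a, r.id_b, r.Ks, config.rate_r)
            for r in results
            if r.filter_status == "retained"
        ]
        t_by_pair = {(e.id_a, e.id_b): e.t_mya for e in estimates}
        rows = []
        for r in results:
            row = asdict(r)
            t = t_by_pair.get((r.id_a, r.id_b))
            row["t_mya"] = "" if t is None else f"{t:.4f}"
            rows.append(row)
        ugio.write_tsv(outdir / "kaks.tsv", rows)
        ids = [g.id for g in genes]
        ugio.write_tsv(
            outdir / "time_matrix.tsv",
            time_matrix_rows(estimates, ids),
            ["id"] + ids[:-1],
        )
        report["clock"] = {"n_dated_pairs": len(estimates), "rate_r": config.rate_r}

    # -- motif scan ---------------------------------------------------------
    hits = []
    windows: dict[str, str] = {}
    with _stage("motif"):
        seeds = list(config.motif_seeds)
        if not seeds and config.simulation is not None and config.simulation.motif:
            seeds = [config.simulation.motif[0]]
        if seeds:
            profile = build_profile(seeds)
            for g in genes:
                for h in scan_pspg(
                    g.id, g.protein, profile, flank_len=config.motif_flank
                ):
                    hits.append(h)
                    windows[g.id] = h.window
            ugio.write_tsv(
                outdir / "motif_hits.tsv",
                [asdict(h) for h in hits],
                ["protein_id", "start", "end", "score", "window", "flank_up", "flank_down"],
            )
            if windows:
                ugio.write_fasta(outdir / "motif_windows.fasta", windows)
        report["motif"] = {"n_hits": len(hits)}

    # -- phylogeny ----------------------------------------------------------
    with _stage("phylogeny"):
        tree = None
        supports = {}
        if len(genes) >= 3:
            if len(windows) == len(genes):  # fixed-length motif windows
                dm = p_distance(windows)
                tree = nj_tree(dm)
                supports = bootstrap(
                    windows, n_reps=config.bootstrap_reps, seed=config.seed
                )
                tree.supports = supports
            else:
                pd_aln = {
                    k: 1.0 - a.identity for k, a in alignments.items()
                }
                import numpy as np

                ids = [g.id for g in genes]
                d = np.zeros((len(ids), len(ids)))
                for i, a in enumerate(ids):
                    for j in range(i + 1, len(ids)):
                        d[i, j] = d[j, i] = pd_aln[tuple(sorted((a, ids[j])))]
                from .phylogeny import DistanceMatrix

                tree = nj_tree(DistanceMatrix(ids, d))
            (outdir / "tree.nwk").write_text(tree.newick() + "\n")
        report["phylogeny"] = {
            "n_taxa": len(genes) if tree else 0,
            "n_supported_splits": len(supports),
        }

    # -- summaries ----------------------------------------------------------
    with _stage("summary"):
        retained = [r for r in results if r.filter_status == "retained"]
        if retained:
            summ = ks_summary(results, config.bin_width)
            report["ks_summary"] = summ.as_dict()
            ugio.write_tsv(outdir / "ks_summary.tsv", [summ.as_dict()])
        if truth is not None:
            truth_t = {tuple(sorted((p.id_a, p.id_b))): p.true_t_mya for p in truth.pairs}
            errors = [
                abs(t_by_pair[k] - truth_t[k]) / truth_t[k]
                for k in t_by_pair
                if truth_t.get(k)
            ]
            import statistics

            med = statistics.median(errors) if errors else None
            report["recovery"] = {
                "n_compared": len(errors),
                "median_abs_rel_time_error": med,
            }

    with _stage("metadata"):
        meta = {
            "seed": config.seed,
            "rate_r": config.rate_r,
            "score_threshold": report["duplication"]["score_threshold"],
            "min_fraction": config.min_fraction,
            "neutral_band": config.neutral_band,
            "bin_width": config.bin_width,
            "bootstrap_reps": config.bootstrap_reps,
        }
        with open(outdir / "run_metadata.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)

    return report
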