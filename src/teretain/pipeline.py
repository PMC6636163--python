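"""End-to-end orchestration: simulate -> age -> gene orthology -> TE
orthology -> retention analysis -> mobilome, with a single YAML-able config,
a run manifest and (for simulated runs) truth-based evaluation.

All stage products are written as TSV under the run directory; reruns with
an identical config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .formats import (
    AnnotatedGenome,
    GeneIndex,
    classify_te_location,
    nearest_gene_distance,
    read_genome_annotation,
    write_fasta,
    write_genome_annotation,
)
from .gene_orthology import build_proteome, rbh_ortholog_map
from .mobilome import discover_insertions, genotype_population
from .retention import (
    SiRNAProfile,
    compare_distances,
    compare_lengths,
    compare_locations,
    compare_superfamilies,
    methylation_group_test,
    sirna_active,
    te_methylation_percent,
)  # noqa: F401 - re-used by run_retention_reports below
from .synthetic import (
    SimulationConfig,
    TruthTable,
    evolve_pair,
    simulate_ancestor,
    simulate_side_tables,
)
from .te_age import age_summary
from .te_orthology import (
    OrthologyCall,
    OrthologyThresholds,
    run_pairwise,
)

log = logging.getLogger("teretain")

__all__ = ["PipelineConfig", "TruthEvaluation", "run_full_pipeline", "evaluate_against_truth"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; unknown YAML keys are rejected."""

    seed: int = 0
    out_dir: str = "te-retain-run"
    simulate: bool = True
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # inputs used when simulate is false
    genome_a_fasta: str | None = None
    genome_a_gff3: str | None = None
    genome_b_fasta: str | None = None
    genome_b_gff3: str | None = None
    # thresholds
    max_segment: int = 70_000
    e_max: float = 1e-10
    min_hit_identity: float = 80.0
    require_same_family: bool = True
    age_threshold: float = 90.0
    rbh_min_identity: float = 85.0
    rbh_min_coverage: float = 60.0
    sirna_min_rpm: float = 5.0
    sirna_min_cov: float = 0.10
    methylation_site_threshold: float = 0.20
    mobilome_min_discovery: int = 10
    mobilome_min_genotype: int = 2
    run_side_tables: bool = True
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        sim_raw = raw.pop("simulation", {})
        sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
        sim_unknown = set(sim_raw) - sim_known
        if sim_unknown:
            raise ValueError(f"unknown simulation key(s): {sorted(sim_unknown)}")
        if "superfamily_weights" in sim_raw:
            sim_raw["superfamily_weights"] = dict(sim_raw["superfamily_weights"])
        seed = raw.get("seed", 0)
        sim_raw.setdefault("seed", seed)
        return cls(simulation=SimulationConfig(**sim_raw), **raw)

    def config_hash(self) -> str:
        """Hash of the semantic configuration (paths/verbosity excluded)."""
        payload = dataclasses.asdict(self)
        for key in ("out_dir", "verbosity"):
            payload.pop(key, None)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()

    def thresholds(self) -> OrthologyThresholds:
        return OrthologyThresholds(
            max_segment=self.max_segment,
            e_max=self.e_max,
            min_identity=self.min_hit_identity,
            require_same_family=self.require_same_family,
            age_threshold=self.age_threshold,
        )


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

@dataclass
class TruthEvaluation:
    precision: float
    recall: float
    confusion: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [("precision", self.precision), ("recall", self.recall)]
        rows += sorted(self.confusion.items())
        return pd.DataFrame(rows, columns=["metric", "value"])


def evaluate_against_truth(
    calls: list[OrthologyCall], truth: TruthTable, direction: str = "a"
) -> TruthEvaluation:
    """Score orthology calls against the simulator's truth table.

    Orthologous is the positive class.  Truth rows expecting
    ``not_interrogated`` (young lineage-specific copies, double deletions)
    and calls discarded by the framing rules are excluded, so the confusion
    counts reconcile to the interrogated total.
    """
    expected = truth.status_by_te(direction)
    missing = [c.te_id for c in calls if c.te_id not in expected]
    if missing:
        raise ValueError(
            f"calls reference TE id(s) absent from the truth table: {missing[:10]}"
        )
    tp = fp = fn = tn = discarded = skipped = 0
    for c in calls:
        exp = expected[c.te_id]
        if exp == "not_interrogated":
            skipped += 1
            continue
        if c.status == "discarded":
            discarded += 1
            continue
        called_pos = c.status == "orthologous"
        true_pos = exp == "orthologous"
        if called_pos and true_pos:
            tp += 1
        elif called_pos:
            fp += 1
        elif true_pos:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return TruthEvaluation(
        precision,
        recall,
        {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
         "discarded": discarded, "not_interrogated": skipped},
    )


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _calls_frame(calls: list[OrthologyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        hit = c.best_hit
        rows.append(
            {
                "te_id": c.te_id,
                "status": c.status,
                "discard_reason": c.discard_reason,
                "kind": c.kind or "",
                "age_class": c.age_class or "",
                "identity_to_consensus": (
                    round(c.identity_to_consensus, 3)
                    if c.identity_to_consensus is not None else ""
                ),
                "matched_te_id": c.matched_te_id or "",
                "hit_evalue": f"{hit.e_value:.3e}" if hit else "",
                "hit_identity": round(hit.identity, 2) if hit else "",
                "hit_score": hit.score if hit else "",
            }
        )
    return pd.DataFrame(rows)


def _report_row(rep) -> dict:
    return {
        "factor": rep.factor,
        "test": rep.test,
        "statistic": round(rep.statistic, 6),
        "df": rep.df if rep.df is not None else "",
        "p_value": f"{rep.p_value:.6e}",
        "code": rep.code,
        "groups": json.dumps(rep.groups, sort_keys=True, default=float),
        "extra": json.dumps(rep.extra, sort_keys=True, default=float),
    }


def _old_te_groups(genome: AnnotatedGenome, calls, age_threshold: float):
    """Old orthologous / old non-orthologous TECopy lists for one genome."""
    te_by_id = {t.te_id: t for t in genome.tes}
    orth, non = [], []
    for c in calls:
        te = te_by_id.get(c.te_id)
        if te is None or te.identity_to_consensus is None:
            continue
        if te.identity_to_consensus >= age_threshold:
            continue
        if c.status == "orthologous":
            orth.append(te)
        elif c.status == "non_orthologous":
            non.append(te)
    return orth, non


def run_retention_reports(
    genome: AnnotatedGenome,
    calls: list[OrthologyCall],
    age_threshold: float = 90.0,
    sirna: pd.DataFrame | None = None,
    methylation: pd.DataFrame | None = None,
    sirna_min_rpm: float = 5.0,
    sirna_min_cov: float = 0.10,
    methylation_site_threshold: float = 0.20,
) -> list:
    """The Fig. 5-style factor battery on old TEs of one genome."""
    orth, non = _old_te_groups(genome, calls, age_threshold)
    reports = []
    if not orth or not non:
        warnings.warn("a call group is empty; no factor reports produced")
        return reports
    index = GeneIndex(genome.genes)
    reports.extend(compare_superfamilies(orth, non).values())
    reports.append(compare_lengths([t.length for t in orth], [t.length for t in non]))
    loc_o = [classify_te_location(t, index) for t in orth]
    loc_n = [classify_te_location(t, index) for t in non]
    rep1, rep2 = compare_locations(loc_o, loc_n, genome)
    reports.extend([rep1, rep2])
    d_o = [nearest_gene_distance(t, index) for t, l in zip(orth, loc_o) if l == "intergenic"]
    d_n = [nearest_gene_distance(t, index) for t, l in zip(non, loc_n) if l == "intergenic"]
    try:
        reports.append(compare_distances(d_o, d_n))
    except ValueError:
        warnings.warn("distance contrast skipped (too few intergenic TEs)")

    if sirna is not None:
        from .retention import FactorReport, chi2_2x2

        prof = {
            r.te_id: SiRNAProfile(r.te_id, r.reads_per_million, r.covered_fraction)
            for r in sirna.itertuples()
        }
        for genic_flag, tag in ((True, "genic"), (False, "intergenic")):
            sel_o = [t for t, l in zip(orth, loc_o) if (l != "intergenic") == genic_flag]
            sel_n = [t for t, l in zip(non, loc_n) if (l != "intergenic") == genic_flag]
            act_o = sum(
                sirna_active(prof[t.te_id], sirna_min_rpm, sirna_min_cov)
                for t in sel_o if t.te_id in prof
            )
            act_n = sum(
                sirna_active(prof[t.te_id], sirna_min_rpm, sirna_min_cov)
                for t in sel_n if t.te_id in prof
            )
            n_o = sum(t.te_id in prof for t in sel_o)
            n_n = sum(t.te_id in prof for t in sel_n)
            if min(n_o, n_n) == 0:
                continue
            table = np.array([[act_o, n_o - act_o], [act_n, n_n - act_n]], float)
            stat, p = chi2_2x2(table)
            reports.append(
                FactorReport(
                    factor=f"sirna_active:{tag}", test="chi2_1df", statistic=stat,
                    p_value=p, df=1, table=table,
                    groups={
                        "orthologous": {"n": n_o, "active_fraction": act_o / n_o},
                        "non_orthologous": {"n": n_n, "active_fraction": act_n / n_n},
                    },
                )
            )

    if methylation is not None:
        groups: dict[str, list[float]] = {
            "orthologous_genic": [], "non_orthologous_genic": [],
            "orthologous_intergenic": [], "non_orthologous_intergenic": [],
        }
        for te_list, locs, label in ((orth, loc_o, "orthologous"), (non, loc_n, "non_orthologous")):
            for t, l in zip(te_list, locs):
                pct = te_methylation_percent(t, methylation, methylation_site_threshold)
                if pct is None:
                    continue
                tag = "genic" if l != "intergenic" else "intergenic"
                groups[f"{label}_{tag}"].append(pct)
        try:
            reports.append(methylation_group_test(groups))
        except ValueError:
            warnings.warn("methylation group test skipped (empty groups)")
    return reports


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing all products under ``config.out_dir``.

    Returns a result bundle with the in-memory objects and the paths written.
    Stage failures raise with the failing stage named; files already written
    are retained.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {"out_dir": str(out)}
    stage = "setup"
    try:
        stage = "simulate" if config.simulate else "load-inputs"
        truth = None
        side = None
        if config.simulate:
            sim = config.simulation
            ancestor, library = simulate_ancestor(sim)
            genome_a, genome_b, truth = evolve_pair(ancestor, library, sim)
            write_genome_annotation(genome_a, out / "genomeA.fa", out / "genomeA.gff3")
            write_genome_annotation(genome_b, out / "genomeB.fa", out / "genomeB.gff3")
            write_fasta(out / "library.fa", library)
            truth.write_tsv(out / "truth.tsv")
            if config.run_side_tables:
                sirna, methylation, expression, mobilome_ev = simulate_side_tables(
                    genome_a, genome_b, truth, sim
                )
                side = dict(sirna=sirna, methylation=methylation,
                            expression=expression, mobilome=mobilome_ev)
                sirna.to_csv(out / "sirna.tsv", sep="\t", index=False)
                methylation.to_csv(out / "methylation.tsv", sep="\t", index=False)
                expression.to_csv(out / "expression.tsv", sep="\t", index=False)
                mobilome_ev.to_csv(out / "mobilome_evidence.tsv", sep="\t", index=False)
        else:
            if not all([config.genome_a_fasta, config.genome_a_gff3,
                        config.genome_b_fasta, config.genome_b_gff3]):
                raise ValueError("simulate=false requires genome A/B fasta+gff3 paths")
            genome_a = read_genome_annotation(config.genome_a_fasta, config.genome_a_gff3, "A")
            genome_b = read_genome_annotation(config.genome_b_fasta, config.genome_b_gff3, "B")
        result.update(genome_a=genome_a, genome_b=genome_b, truth=truth)

        stage = "age"
        for label, genome in (("A", genome_a), ("B", genome_b)):
            classes, hist = age_summary(genome, config.age_threshold)
            pd.DataFrame(
                [(c.te_id, round(c.identity, 3), c.age_class) for c in classes],
                columns=["te_id", "identity", "age_class"],
            ).to_csv(out / f"age_{label}.tsv", sep="\t", index=False)
            result[f"age_hist_{label}"] = hist
        log.info("age: young fractions A=%.1f%% B=%.1f%%",
                 result["age_hist_A"].young_fraction_percent,
                 result["age_hist_B"].young_fraction_percent)

        stage = "gene-orthology"
        ortho_map = rbh_ortholog_map(
            build_proteome(genome_a), build_proteome(genome_b),
            config.rbh_min_identity, config.rbh_min_coverage,
        )
        pd.DataFrame(
            [(p.gene_a, p.gene_b, round(p.identity, 2), round(p.coverage_a, 2),
              round(p.coverage_b, 2), p.score) for p in ortho_map.pairs],
            columns=["gene_a", "gene_b", "identity", "coverage_a", "coverage_b", "score"],
        ).to_csv(out / "ortholog_map.tsv", sep="\t", index=False)
        result["ortholog_map"] = ortho_map
        log.info("gene-orthology: %d anchor pairs", len(ortho_map))

        stage = "te-orthology"
        pairwise = run_pairwise(genome_a, genome_b, ortho_map, config.thresholds())
        _calls_frame(pairwise.calls_a).to_csv(out / "calls_A.tsv", sep="\t", index=False)
        _calls_frame(pairwise.calls_b).to_csv(out / "calls_B.tsv", sep="\t", index=False)
        summary_rows = []
        for direction, s in (("A_vs_B", pairwise.summary_a), ("B_vs_A", pairwise.summary_b)):
            summary_rows += [
                (direction, "old_orthologous", s.old_orthologous),
                (direction, "young_orthologous", s.young_orthologous),
                (direction, "total_orthologous", s.total_orthologous),
                (direction, "old_non_orthologous", s.old_non_orthologous),
                (direction, "young_non_orthologous", s.young_non_orthologous),
                (direction, "total_non_orthologous", s.total_non_orthologous),
                (direction, "discarded", s.discarded),
            ]
        pd.DataFrame(summary_rows, columns=["direction", "category", "count"]).to_csv(
            out / "orthology_summary.tsv", sep="\t", index=False
        )
        result["pairwise"] = pairwise

        stage = "retention-analysis"
        reports = run_retention_reports(
            genome_a, pairwise.calls_a, config.age_threshold,
            sirna=side["sirna"] if side else None,
            methylation=side["methylation"] if side else None,
            sirna_min_rpm=config.sirna_min_rpm,
            sirna_min_cov=config.sirna_min_cov,
            methylation_site_threshold=config.methylation_site_threshold,
        )
        pd.DataFrame([_report_row(r) for r in reports]).to_csv(
            out / "factor_reports.tsv", sep="\t", index=False
        )
        result["factor_reports"] = reports

        if side is not None:
            stage = "mobilome"
            candidates = discover_insertions(side["mobilome"], config.mobilome_min_discovery)
            callset = genotype_population(
                candidates, side["mobilome"], config.mobilome_min_genotype
            )
            candidates.to_csv(out / "mobilome_calls.tsv", sep="\t", index=False)
            callset.superfamily_composition.rename("fraction").to_csv(
                out / "mobilome_composition.tsv", sep="\t"
            )
            callset.frequency_spectrum.rename("n_sites").to_csv(
                out / "mobilome_frequency_spectrum.tsv", sep="\t"
            )
            result["mobilome"] = callset

        if truth is not None:
            stage = "truth-evaluation"
            eval_a = evaluate_against_truth(pairwise.calls_a, truth, "a")
            eval_b = evaluate_against_truth(pairwise.calls_b, truth, "b")
            pd.concat(
                [eval_a.to_frame().assign(direction="A_vs_B"),
                 eval_b.to_frame().assign(direction="B_vs_A")]
            ).to_csv(out / "truth_evaluation.tsv", sep="\t", index=False)
            result["truth_eval_a"] = eval_a
            result["truth_eval_b"] = eval_b
            log.info("truth: precision=%.3f recall=%.3f (A vs B)",
                     eval_a.precision, eval_a.recall)

        stage = "manifest"
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
            "stages": ["simulate" if config.simulate else "load-inputs", "age",
                       "gene-orthology", "te-orthology", "retention-analysis",
                       "mobilome", "truth-evaluation", "manifest"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        result["manifest"] = manifest
        return result
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
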