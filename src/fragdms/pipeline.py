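"""End-to-end orchestration of the synthetic dual-selection experiment.

A :class:`PipelineConfig` fully determines a run: the reference, the two
libraries (a high-rate library for the phage selection and a low-rate
library for the maltodextrin selection), the replicate layout (three
biological x two technical by default), selection and sequencing
parameters, and every downstream threshold.  All randomness derives from
the global seed through a documented counter scheme, so two runs of the
same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import field
import hashlib
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import fragproc, scoring, syndata
from .classify import ThresholdConfig
from .reference import ReferenceAmplicon, demo_reference

logger = logging.getLogger("fragdms")

SELECTIONS = ("lambda", "malt")
_SEL_CODE = {"lambda": 1, "malt": 2}
_STAGE_CODE = {"library": 1, "fitness": 2, "selection": 3, "sequencing": 4}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and replicate id."""


def stage_rng(
    seed: int, stage: str, selection: str = "lambda", bio: int = 0, tech: int = 0
) -> np.random.Generator:
    """Deterministic per-(stage, selection, replicate) generator.

    The stream is seeded from the tuple (global seed, stage code, selection
    code, biological index, technical index), so replicates are independent
    but reproducible.
    """
    return np.random.default_rng(
        [int(seed), _STAGE_CODE[stage], _SEL_CODE.get(selection, 0), bio, tech]
    )


@dataclasses.dataclass
class SelectionConfig:
    """Per-selection library, growth, and sequencing depth parameters."""

    n_variants: int
    per_base_rate: float
    generations: float
    n_fragments: int


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    reference_fasta: str | None = None  # None -> bundled demo reference
    n_biological: int = 3
    n_technical: int = 2
    bottleneck: int = 200_000
    read_length: int = 38
    per_base_seq_error: float = 0.002
    duplication: tuple = ("shifted_poisson", 5, 3.0)
    fragment_length_median: float = 63.0
    fragment_length_sigma: float = 0.35
    pseudocount: float = 0.1
    min_raw: int = 5
    min_mean_ctrl: float = 5.0
    max_mismatch_frac: float = 0.1
    malt_formula: str = "prose"
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    refined_t_lambda: float = 0.35
    ratio_grid: tuple = tuple(np.round(np.arange(0.05, 1.0001, 0.05), 2))
    write_fragments: str = "first"  # all | first | none
    selections: dict = field(
        default_factory=lambda: {
            "lambda": SelectionConfig(
                n_variants=10_000,
                per_base_rate=0.0052,
                generations=10.0,
                n_fragments=150_000,
            ),
            "malt": SelectionConfig(
                n_variants=20_000,
                per_base_rate=0.00063,
                generations=6.0,
                n_fragments=350_000,
            ),
        }
    )

    def __post_init__(self) -> None:
        if self.n_biological < 1 or self.n_technical < 1:
            raise ValueError("replicate layout must be at least 1x1")
        for name in SELECTIONS:
            if name not in self.selections:
                raise ValueError(f"missing selection config for {name!r}")
            if isinstance(self.selections[name], dict):
                self.selections[name] = SelectionConfig(**self.selections[name])

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["thresholds"] = dataclasses.asdict(self.thresholds)
        out["duplication"] = list(self.duplication)
        out["ratio_grid"] = [float(t) for t in self.ratio_grid]
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = ThresholdConfig(**data["thresholds"])
        if "duplication" in data:
            data["duplication"] = tuple(data["duplication"])
        if "ratio_grid" in data:
            data["ratio_grid"] = tuple(data["ratio_grid"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def demo_config(seed: int = 0) -> PipelineConfig:
    """A minutes-scale configuration for smoke tests and the CLI demo."""
    return PipelineConfig(
        seed=seed,
        n_biological=1,
        n_technical=2,
        selections={
            "lambda": SelectionConfig(
                n_variants=2000, per_base_rate=0.0052, generations=10.0,
                n_fragments=40_000,
            ),
            "malt": SelectionConfig(
                n_variants=100, per_base_rate=0.00063, generations=6.0,
                n_fragments=25_000,
            ),
        },
        write_fragments="first",
    )


# ---------------------------------------------------------------------------
# Result container


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    ref: ReferenceAmplicon
    models: dict
    libraries: dict
    true_effects: pd.DataFrame
    enrichments: dict  # selection -> {replicate: DataFrame}
    scores: dict  # selection -> per-replicate scored tables
    mean_scores: dict  # selection -> averaged ScoreTable
    calls: pd.DataFrame
    refined_calls: pd.DataFrame
    ratio_curve: pd.DataFrame
    per_residue: dict
    summary: dict
    report: str


# ---------------------------------------------------------------------------
# Stages


def _simulate_counts(
    config: PipelineConfig, ref: ReferenceAmplicon, selection: str,
    library, fitnesses, index: fragproc.ReferenceIndex, outdir: Path | None,
) -> dict[str, tuple[fragproc.CountTable, fragproc.CountTable]]:
    """Selection + sequencing + read processing for all replicates of one
    selection; returns {replicate: (selected, control) count tables}."""
    sel_cfg: SelectionConfig = config.selections[selection]
    seqs = syndata.variant_sequences(ref, library)
    pre = np.array([v.abundance for v in library])
    tables: dict[str, tuple[fragproc.CountTable, fragproc.CountTable]] = {}
    for bio in range(1, config.n_biological + 1):
        post = {}
        for arm, condition in (("sel", selection), ("ctrl", "control")):
            rng = stage_rng(config.seed, "selection", selection, bio,
                            0 if arm == "sel" else 1)
            post[arm] = syndata.simulate_selection(
                pre, fitnesses, condition, sel_cfg.generations,
                bottleneck=config.bottleneck, rng=rng,
            )
        for tech in range(1, config.n_technical + 1):
            rep = f"b{bio}t{tech}"
            arm_tables = {}
            for arm_i, arm in enumerate(("sel", "ctrl")):
                seq_spec = syndata.SequencingSpec(
                    n_fragments=sel_cfg.n_fragments,
                    read_length=config.read_length,
                    per_base_error=config.per_base_seq_error,
                    fragment_length_median=config.fragment_length_median,
                    fragment_length_sigma=config.fragment_length_sigma,
                    duplication=config.duplication,
                )
                rng = stage_rng(config.seed, "sequencing", selection, bio,
                                10 * tech + arm_i)
                try:
                    pairs, _truth = syndata.simulate_reads(
                        library, post[arm], ref, seq_spec, rng=rng, seqs=seqs
                    )
                    fragments, table, log = fragproc.process_read_pairs(
                        pairs, index, min_raw=config.min_raw,
                        max_mismatch_frac=config.max_mismatch_frac,
                    )
                except Exception as exc:  # pragma: no cover - defensive
                    raise PipelineError(
                        f"stage sequencing failed for selection={selection} "
                        f"replicate={rep} arm={arm}: {exc}"
                    ) from exc
                logger.info(
                    "%s %s %s: %s", selection, rep, arm, log
                )
                arm_tables[arm] = (fragments, table)
                if outdir is not None:
                    write_this = config.write_fragments == "all" or (
                        config.write_fragments == "first" and rep == "b1t1"
                    )
                    if write_this:
                        frame = fragproc.fragments_to_frame(
                            fragments, ref.cds_start
                        )
                        _write_tsv(
                            frame,
                            outdir / f"fragments_{selection}_{rep}_{arm}.tsv",
                            config,
                        )
                    table.to_tsv(
                        outdir / f"counts_{selection}_{rep}_{arm}.tsv",
                        header_lines=_header(config),
                    )
            tables[rep] = (arm_tables["sel"][1], arm_tables["ctrl"][1])
    return tables


def _header(config: PipelineConfig) -> list[str]:
    return [f"fragdms config_hash={config.config_hash()} seed={config.seed}"]


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index)


def _score_selection(
    config: PipelineConfig,
    catalog: pd.DataFrame,
    tables: dict[str, tuple[fragproc.CountTable, fragproc.CountTable]],
    selection: str,
) -> tuple[dict, dict, pd.DataFrame]:
    enrichments = {}
    for rep, (sel_table, ctrl_table) in tables.items():
        try:
            enrichments[rep] = scoring.compute_enrichment(
                sel_table, ctrl_table, pseudocount=config.pseudocount
            )
        except Exception as exc:
            raise PipelineError(
                f"stage score failed for selection={selection} replicate={rep}: {exc}"
            ) from exc
    filtered = scoring.filter_by_input(enrichments, config.min_mean_ctrl)
    scored = {}
    for rep, table in filtered.items():
        try:
            scored[rep] = scoring.scale_to_functional(
                table, catalog, selection=selection,
                malt_formula=config.malt_formula, replicate=rep,
            )
        except Exception as exc:
            raise PipelineError(
                f"stage score failed for selection={selection} replicate={rep}: {exc}"
            ) from exc
    mean_scores = scoring.average_replicates(scored)
    return enrichments, scored, mean_scores


def make_report(
    mean_scores: dict,
    calls: pd.DataFrame,
    refined_calls: pd.DataFrame,
    ratio_curve: pd.DataFrame,
    summary: dict,
) -> str:
    """Plain-markdown run summary; every number re-derivable from the TSVs."""
    lines = ["# fragdms run report", ""]
    lines.append("## Per-class score medians")
    for selection, table in mean_scores.items():
        med = table.groupby("effect_class")["F_mean"].median()
        for effect, value in med.items():
            lines.append(f"- median F_{selection}[{effect}] = {value:.3f}")
    lines.append("")
    lines.append("## Distribution tests (two-sample KS, asymptotic p)")
    for name, (d, p) in summary["ks_tests"].items():
        lines.append(f"- {name}: D = {d:.3f}, p = {p:.3g}")
    lines.append("")
    lines.append("## Joint classification")
    lines.append(
        f"- syn/nonsense accuracy of (F_malt + F_lambda)/2 >= "
        f"{summary['t_joint']}: {summary['joint_accuracy']:.3f}"
    )
    gi = summary.get("gaussian_intersection_malt")
    if gi is not None:
        lines.append(f"- Gaussian-intersection threshold (malt syn vs stop): {gi:.3f}")
    lines.append("")
    lines.append("## Mal+/Mal- ratio over lambda thresholds")
    lines.append(ratio_curve.to_string(index=False))
    lines.append("")
    n_cand = summary["n_lambda_r_mal_plus"]
    lines.append("## Resistant-but-transporting candidates")
    if n_cand:
        lines.append(
            f"- {n_cand} missense mutations called resistant (F_lambda < "
            f"{summary['refined_t_lambda']}) and Mal+ (F_malt >= "
            f"{summary['t_malt']})"
        )
    else:
        lines.append("- zero candidates at the refined threshold")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(
    config: PipelineConfig, outdir: str | Path | None = None
) -> PipelineResult:
    """Run simulate -> count -> score (both selections) -> classify -> report.

    When ``outdir`` is given, every stage's tables are written there as TSV
    with a header line naming the config hash and seed.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    if config.reference_fasta is not None:
        ref = ReferenceAmplicon.from_fasta(config.reference_fasta)
    else:
        ref = demo_reference()
    if out is not None:
        ref.to_fasta(out / "reference.fasta")
    catalog = scoring.mutation_catalog(ref)
    index = fragproc.ReferenceIndex(ref)

    model_rng = stage_rng(config.seed, "fitness")
    model = syndata.default_fitness_model(
        ref, seed=int(model_rng.integers(2**31))
    )
    true_effects = syndata.true_mutation_effects(model, ref)

    libraries, models = {}, {"shared": model}
    enrichments, scores, mean_scores = {}, {}, {}
    for selection in SELECTIONS:
        sel_cfg = config.selections[selection]
        lib_rng = stage_rng(config.seed, "library", selection)
        try:
            library = syndata.generate_library(
                ref,
                syndata.LibrarySpec(
                    n_variants=sel_cfg.n_variants,
                    per_base_rate=sel_cfg.per_base_rate,
                ),
                rng=lib_rng,
            )
        except Exception as exc:
            raise PipelineError(
                f"stage simulate failed for selection={selection}: {exc}"
            ) from exc
        fitnesses = syndata.library_trait_fitness(library, model, ref)
        libraries[selection] = library
        if out is not None:
            _write_tsv(
                syndata.library_truth_frame(library, fitnesses, ref),
                out / f"ground_truth_{selection}.tsv",
                config,
            )
        tables = _simulate_counts(
            config, ref, selection, library, fitnesses, index, out
        )
        enrichments[selection], scores[selection], mean_scores[selection] = (
            _score_selection(config, catalog, tables, selection)
        )
        if out is not None:
            frame = mean_scores[selection].reset_index()
            frame["mutation"] = [
                f"{cp}:{r}>{a}"
                for cp, r, a in zip(frame["cds_pos"], frame["ref"], frame["alt"])
            ]
            _write_tsv(frame, out / f"scores_{selection}.tsv", config)

    calls = _classify.call_phenotypes(
        mean_scores["lambda"], mean_scores["malt"], config.thresholds
    )
    refined = _classify.call_phenotypes(
        mean_scores["lambda"],
        mean_scores["malt"],
        ThresholdConfig(
            t_lambda=config.refined_t_lambda,
            t_malt=config.thresholds.t_malt,
            t_joint=config.thresholds.t_joint,
        ),
    )
    ratio_curve = _classify.mal_ratio_curve(
        calls, list(config.ratio_grid), t_malt=config.thresholds.t_malt
    )
    per_residue = {
        selection: _classify.per_residue_summary(mean_scores[selection])
        for selection in SELECTIONS
    }

    summary: dict = {
        "t_joint": config.thresholds.t_joint,
        "t_malt": config.thresholds.t_malt,
        "refined_t_lambda": config.refined_t_lambda,
    }
    ks_tests = {}
    for selection in SELECTIONS:
        table = mean_scores[selection]
        classes = {
            eff: table.loc[table["effect_class"] == eff, "F_mean"]
            for eff in ("synonymous", "missense", "nonsense")
        }
        for a, b in (("synonymous", "nonsense"), ("synonymous", "missense")):
            if len(classes[a]) and len(classes[b]):
                ks_tests[f"{selection}: {a} vs {b}"] = _classify.ks_compare(
                    classes[a], classes[b]
                )
        if selection == "malt":
            syn = classes["synonymous"]
            stop = classes["nonsense"]
            if len(syn.unique()) > 1 and len(stop.unique()) > 1:
                summary["gaussian_intersection_malt"] = (
                    _classify.gaussian_intersection_threshold(syn, stop)
                )
    summary["ks_tests"] = ks_tests
    summary["joint_accuracy"] = _classify.classification_accuracy(calls)
    candidates = refined[
        (refined["effect_class"] == "missense")
        & (refined["lambda_call"] == _classify.LAMBDA_RESISTANT)
        & (refined["malt_call"] == _classify.MAL_PLUS)
    ]
    summary["n_lambda_r_mal_plus"] = int(len(candidates))

    report = make_report(mean_scores, calls, refined, ratio_curve, summary)

    if out is not None:
        _write_tsv(calls.reset_index(), out / "calls.tsv", config)
        _write_tsv(ratio_curve, out / "ratio_curve.tsv", config)
        for selection in SELECTIONS:
            _write_tsv(
                per_residue[selection],
                out / f"per_residue_{selection}.tsv",
                config,
            )
        (out / "report.md").write_text(report)

    return PipelineResult(
        config=config,
        ref=ref,
        models=models,
        libraries=libraries,
        true_effects=true_effects,
        enrichments=enrichments,
        scores=scores,
        mean_scores=mean_scores,
        calls=calls,
        refined_calls=refined,
        ratio_curve=ratio_curve,
        per_residue=per_residue,
        summary=summary,
        report=report,
    )
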