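"""End-to-end orchestration: filter -> normalise -> RUV -> DE -> classify -> enrich.

The irradiation and FACS datasets are analysed separately (their technical
structure differs), each with its own CPM filter, size factors, RUV step
(defaults k = 3 for irradiation, k = 1 for FACS, with empirical negative
controls when none are supplied) and exact NB contrasts.  The category
classifier then combines the per-contrast results, and annotation terms are
scored for fold enrichment in every category.  All stage outputs are written
as TSV plus a machine-readable JSON summary; runs are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as nio
from .categories import CategorySets, ClassifierParams, build_categories
from .de import (
    DEResult,
    cpm_filter,
    empirical_controls,
    estimate_dispersion,
    estimate_size_factors,
    nb_exact_test,
    ruv_adjust,
)
from .enrichment import AnnotationMap, enrichment_report, read_annotation
from .slfinder import classify_transspliced, kmer_census, reconstruct_leader

log = logging.getLogger("neoblastsig")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Paths and parameters of one reproducible run (flat YAML-serialisable)."""

    counts: str | None = None
    samples: str | None = None
    annotations: str | None = None
    transcripts: str | None = None
    out_dir: str = "neoblastsig_out"
    alpha: float = 0.05
    fold_threshold: float = 2.0
    germline_combine: str = "and"
    min_cpm: float = 1.0
    min_samples: int = 3
    prior_df: float = 10.0
    ruv_k_irradiation: int = 3
    ruv_k_facs: int = 1
    sl_k: int = 19
    sl_window: int = 100
    sl_min_match_len: int = 15
    sl_max_mismatch: int = 1
    sl_search_window: int = 30
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def classifier_params(self) -> ClassifierParams:
        return ClassifierParams(
            alpha=self.alpha,
            fold_threshold=self.fold_threshold,
            germline_combine=self.germline_combine,
        )


@dataclass
class DatasetAnalysis:
    results: dict[str, DEResult]
    filtered: pd.DataFrame
    adjusted: pd.DataFrame
    controls: list[str]
    ruv_w: object


@dataclass
class PipelineResult:
    irradiation: DatasetAnalysis | None
    facs: DatasetAnalysis | None
    categories: CategorySets | None
    enrichment: pd.DataFrame | None

    def summary(self, params: dict, seed: int) -> dict:
        out: dict = {"set_sizes": {}, "overlaps": [], "enrichment": [], "params": params, "seed": seed}
        if self.categories is not None:
            out["set_sizes"] = self.categories.set_sizes()
            out["overlaps"] = self.categories.overlaps()
        if self.enrichment is not None:
            out["enrichment"] = json.loads(self.enrichment.to_json(orient="records"))
        return out


def _irradiation_contrasts(sheet: pd.DataFrame) -> list[tuple[str, list[str], list[str]]]:
    base = list(sheet.index[sheet["timepoint_h"] == 0])
    contrasts = []
    for t in sorted(sheet.loc[sheet["timepoint_h"] > 0, "timepoint_h"].unique()):
        grp = list(sheet.index[sheet["timepoint_h"] == t])
        contrasts.append((f"irr_{int(t)}h_vs_0h", grp, base))
    return contrasts


def _facs_contrasts(sheet: pd.DataFrame) -> list[tuple[str, list[str], list[str]]]:
    def gate(cond, g):
        return list(sheet.index[(sheet["condition"] == cond) & (sheet["gate"] == g)])

    contrasts = []
    for cond in ("intact", "juvenile", "head"):
        if gate(cond, "4C") and gate(cond, "2C"):
            contrasts.append((f"{cond}_4C_vs_{cond}_2C", gate(cond, "4C"), gate(cond, "2C")))
    for cond in ("juvenile", "head"):
        if gate("intact", "4C") and gate(cond, "4C"):
            contrasts.append((f"intact_4C_vs_{cond}_4C", gate("intact", "4C"), gate(cond, "4C")))
    return contrasts


def _run_contrasts(counts, contrasts, prior_df, alpha):
    sf = estimate_size_factors(counts)
    results = {}
    for name, grp_a, grp_b in contrasts:
        disp = estimate_dispersion(
            counts[grp_a + grp_b], sf[grp_a + grp_b], prior_df=prior_df, groups=[grp_a, grp_b]
        )
        results[name] = nb_exact_test(
            counts[grp_a + grp_b], sf[grp_a + grp_b], disp, grp_a, grp_b, contrast=name, alpha=alpha
        )
    return results


def analyze_dataset(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    dataset: str,
    ruv_k: int,
    config: PipelineConfig,
    control_ids: list[str] | None = None,
) -> DatasetAnalysis:
    """Filter, normalise, optionally RUV-adjust, and test all contrasts of one dataset."""
    sub_sheet = sheet[sheet["dataset"] == dataset]
    if sub_sheet.empty:
        raise PipelineError(f"no samples for dataset {dataset!r}")
    sub = counts[list(sub_sheet.index)]
    filtered = cpm_filter(sub, min_cpm=config.min_cpm, min_samples=config.min_samples)
    contrasts = (
        _irradiation_contrasts(sub_sheet) if dataset == "irradiation" else _facs_contrasts(sub_sheet)
    )
    if not contrasts:
        raise PipelineError(f"no contrasts derivable for dataset {dataset!r}")

    first_pass = _run_contrasts(filtered, contrasts, config.prior_df, config.alpha)
    controls = control_ids
    adjusted, w = filtered, None
    if ruv_k > 0:
        if controls is None:
            controls = empirical_controls(list(first_pass.values()), filtered.index)
        if len(controls) >= ruv_k + 1:
            adjusted, w = ruv_adjust(filtered, controls, ruv_k)
            results = _run_contrasts(adjusted, contrasts, config.prior_df, config.alpha)
        else:
            log.warning("%s: only %d controls, skipping RUV", dataset, len(controls))
            results = first_pass
            controls = controls or []
    else:
        results = first_pass
        controls = controls or []
    return DatasetAnalysis(results, filtered, adjusted, list(controls), w)


def run_analysis(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    config: PipelineConfig,
    annotation: AnnotationMap | None = None,
) -> PipelineResult:
    """In-memory pipeline over both datasets; returns DE results, categories, enrichment."""
    nio.check_counts_samples(counts, sheet)
    datasets = set(sheet["dataset"])
    irr = facs = None
    if "irradiation" in datasets:
        irr = analyze_dataset(counts, sheet, "irradiation", config.ruv_k_irradiation, config)
    if "facs" in datasets:
        facs = analyze_dataset(counts, sheet, "facs", config.ruv_k_facs, config)

    categories = None
    if irr is not None and facs is not None:
        de_irr = {
            "12h": irr.results["irr_12h_vs_0h"],
            "24h": irr.results["irr_24h_vs_0h"],
            "72h": irr.results["irr_72h_vs_0h"],
        }
        de_facs = {
            "intact": facs.results["intact_4C_vs_intact_2C"],
            "juvenile": facs.results["juvenile_4C_vs_juvenile_2C"],
            "head": facs.results["head_4C_vs_head_2C"],
            "intact_vs_juvenile": facs.results["intact_4C_vs_juvenile_4C"],
            "intact_vs_head": facs.results["intact_4C_vs_head_4C"],
        }
        categories = build_categories(de_irr, de_facs, config.classifier_params())

    enrichment = None
    if annotation is not None and categories is not None:
        universe = set(counts.index)
        enrichment = enrichment_report(categories, annotation, universe=universe)
    return PipelineResult(irr, facs, categories, enrichment)


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """File-level pipeline: read inputs, run all stages, write outputs and summary.

    Eagerly validates every referenced input before any computation, so a
    missing annotation file fails before the DE stage, not after it.
    """
    for attr in ("counts", "samples"):
        if getattr(config, attr) is None:
            raise PipelineError(f"config.{attr} is required")
    for attr in ("counts", "samples", "annotations", "transcripts"):
        path = getattr(config, attr)
        if path is not None and not Path(path).exists():
            raise PipelineError(f"{attr} file not found: {path}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict[str, Path] = {"log": out_dir / "run.log"}
    try:
        from . import __version__

        params = dataclasses.asdict(config)
        log.info("neoblastsig %s", __version__)
        log.info("parameters: %s", json.dumps(params, sort_keys=True))

        counts = nio.read_counts(config.counts)
        sheet = nio.read_sample_sheet(config.samples)
        annotation = read_annotation(config.annotations) if config.annotations else None
        transcripts = nio.read_fasta(config.transcripts) if config.transcripts else None

        result = run_analysis(counts, sheet, config, annotation)

        for ds_name, analysis in (("irradiation", result.irradiation), ("facs", result.facs)):
            if analysis is None:
                continue
            for cname, res in analysis.results.items():
                path = out_dir / f"de_{cname}.tsv"
                nio.write_de_result(res, path)
                manifest[f"de_{cname}"] = path
            log.info("%s: %d clusters tested, controls=%d", ds_name,
                     len(analysis.filtered), len(analysis.controls))

        if result.categories is not None:
            cat_path = out_dir / "categories.tsv"
            result.categories.to_frame().to_csv(cat_path, sep="\t")
            manifest["categories"] = cat_path
            log.info("set sizes: %s", result.categories.set_sizes())
        if result.enrichment is not None:
            enr_path = out_dir / "enrichment.tsv"
            result.enrichment.to_csv(enr_path, sep="\t", index=False)
            manifest["enrichment"] = enr_path

        if transcripts is not None:
            census = kmer_census(transcripts, k=config.sl_k, window=config.sl_window)
            call = reconstruct_leader(census)
            leader_path = out_dir / "leader.fasta"
            with open(leader_path, "w") as fh:
                if call.consensus:
                    fh.write(f">SL_consensus support={call.support}\n{call.consensus}\n")
            manifest["leader"] = leader_path
            log.info("leader consensus: %s (support %d)", call.consensus or "<none>", call.support)
            if call.consensus and len(call.consensus) >= config.sl_min_match_len:
                flags = classify_transspliced(
                    transcripts,
                    call.consensus,
                    min_match_len=config.sl_min_match_len,
                    max_mismatch=config.sl_max_mismatch,
                    search_window=config.sl_search_window,
                )
                rows = []
                for tid, flagged in flags.flags.items():
                    mlen, mstart, mism = flags.details.get(tid, (0, -1, -1))
                    rows.append((tid, int(flagged), mlen, mstart, mism))
                flags_path = out_dir / "transspliced.tsv"
                pd.DataFrame(
                    rows,
                    columns=["transcript_id", "transspliced", "match_len", "match_start", "mismatches"],
                ).to_csv(flags_path, sep="\t", index=False)
                manifest["transspliced"] = flags_path

        summary = result.summary(params, config.seed)
        summary_path = out_dir / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest["summary"] = summary_path
        log.info("done: %d outputs", len(manifest))
    except Exception as exc:  # annotate with the failing stage and re-raise
        log.error("pipeline failed: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest
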