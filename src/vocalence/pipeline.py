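"""Pipeline orchestration and cross-call-type aggregation.

LF and HF calls are analyzed separately (their parameter distributions
differ too much to pool), so dataset-level figures are reported as
weighted averages of the two call types, weighted by the number of
complete-case calls of each type.  This module holds those reporting
operations plus an end-to-end runner: synthesize -> extract features ->
PCA/LMM screen -> pDFA per call type -> aggregate -> (optionally) CNN +
t-SNE, emitting a JSON report with every stage's seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import screening
from .pdfa import PdfaDesign, PdfaResult, run_pdfa
from .synth import SynthSpec, default_spec, synthesize_dataset, write_dataset

__all__ = ["weighted_average", "relative_classification", "dataset_accounting",
           "aggregate_pdfa", "RunConfig", "run_pipeline"]


def weighted_average(values, weights) -> float:
    """Call-count-weighted average of per-call-type percentages.

    ``(v1*w1 + v2*w2) / (w1 + w2)``; rounding happens only at the
    presentation layer.
    """
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    if np.any(weights <= 0):
        raise ValueError("weights must be > 0")
    return float(np.sum(values * weights) / np.sum(weights))


def relative_classification(pct_cross: float, chance_cross: float) -> float:
    """Cross-classification success relative to its permutation chance level."""
    if chance_cross <= 0:
        raise ValueError("chance level must be > 0")
    return float(pct_cross / chance_cross)


def dataset_accounting(total: int, excluded: int) -> int:
    """Calls included in an analysis after dropping incomplete rows."""
    if excluded > total:
        raise ValueError("excluded exceeds total")
    return int(total - excluded)


def aggregate_pdfa(results: dict[str, PdfaResult]) -> dict:
    """Weighted averages across call types, weighted by complete-case counts."""
    types = sorted(results)
    weights = [results[t].n_calls_total for t in types]
    agg = {"call_types": types, "weights": weights}
    for fld in ("pct_classified", "chance_classified",
                "pct_cross_classified", "chance_cross_classified"):
        agg[fld] = weighted_average([getattr(results[t], fld) for t in types], weights)
    agg["relative_cross"] = {t: results[t].relative_cross for t in types}
    total = sum(weights) + sum(results[t].n_dropped_incomplete for t in types)
    agg["n_calls_total"] = total
    agg["n_excluded_incomplete"] = sum(results[t].n_dropped_incomplete for t in types)
    agg["n_calls_included"] = dataset_accounting(total, agg["n_excluded_incomplete"])
    return agg


@dataclass
class RunConfig:
    outdir: str = "vocalence_run"
    n_calls: int = 300
    seed: int = 0
    factor: str = "valence"
    n_permutations: int = 100
    n_selection_reps: int = 20
    run_stats: bool = True
    run_pdfa_stage: bool = True
    run_cnn: bool = False
    cnn_epochs: int = 5
    cnn_trials: int = 2
    run_embedding: bool = False
    perplexity: float | None = None
    write_wavs: bool = False
    spec: SynthSpec | None = None


def _split_pdfa(table: pd.DataFrame, cfg: RunConfig) -> dict[str, PdfaResult]:
    out = {}
    for ctype in ("LF", "HF"):
        sub = table[table["call_type"] == ctype]
        design = PdfaDesign(test_factor=cfg.factor,
                            n_selection_reps=cfg.n_selection_reps,
                            n_permutations=cfg.n_permutations,
                            rng_seed=cfg.seed + (1 if ctype == "HF" else 0))
        try:
            out[ctype] = run_pdfa(sub, design)
        except (ValueError, RuntimeError) as exc:
            warnings.warn(f"pDFA skipped for {ctype}: {exc}")
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages and write ``report.json`` to the outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = cfg.spec or default_spec(rng_seed=cfg.seed, n_calls=cfg.n_calls)
    report: dict = {"seed": cfg.seed, "n_calls": cfg.n_calls, "stages": {}}

    calls, meta = synthesize_dataset(spec, n_calls=cfg.n_calls)
    if cfg.write_wavs:
        write_dataset(calls, meta, outdir / "calls")
    table = feat.extract_table(calls)
    table.to_csv(outdir / "features.csv", index=False)
    report["stages"]["synth"] = {"seed": spec.rng_seed, "n_calls": len(calls)}
    report["stages"]["extract"] = {
        "n_rows": len(table),
        "n_missing_am": int(table["AmpModRate"].isna().sum()),
    }

    if cfg.run_stats:
        stats = {}
        for ctype in ("LF", "HF"):
            entry = {}
            try:
                sel = screening.select_parameters(table, ctype)
                entry["selected"] = sel.selected
            except ValueError as exc:
                warnings.warn(f"PCA skipped for {ctype}: {exc}")
                continue
            entry["lmm"] = {}
            for outcome in entry["selected"]:
                sub = table[table["call_type"] == ctype]
                try:
                    res = screening.fit_valence_lmm(sub, outcome, cfg.factor)
                    entry["lmm"][outcome] = {
                        "marginal_r2": res.marginal_r2,
                        "p_value": res.p_value,
                        "coefficients": {k: float(v) for k, v in res.coefficients.items()},
                    }
                except (ValueError, np.linalg.LinAlgError) as exc:
                    warnings.warn(f"LMM skipped for {ctype}/{outcome}: {exc}")
            stats[ctype] = entry
        report["stages"]["stats"] = stats

    if cfg.run_pdfa_stage:
        results = _split_pdfa(table, cfg)
        per_type = {t: asdict(r) for t, r in results.items()}
        for t, r in results.items():
            per_type[t]["relative_cross"] = r.relative_cross
        report["stages"]["pdfa"] = per_type
        if len(results) == 2:
            report["stages"]["pdfa_weighted"] = aggregate_pdfa(results)

    if cfg.run_cnn:
        from .classifier import SpectrogramConfig, TrainConfig, spectrogram_stack, train_classifier

        scfg = SpectrogramConfig(hop_fraction=0.25)
        X = spectrogram_stack(calls, scfg)
        labels = meta[cfg.factor if cfg.factor in meta.columns else "valence"]
        tcfg = TrainConfig(task=cfg.factor, epochs=cfg.cnn_epochs,
                           n_trials=cfg.cnn_trials, rng_seed=cfg.seed)
        model, classes, trials, summary = train_classifier(X, labels, tcfg)
        report["stages"]["cnn"] = {
            "classes": list(classes),
            "trials": [asdict(t) for t in trials],
            "summary": asdict(summary) if summary else None,
            "seed": cfg.seed,
        }
        if cfg.run_embedding:
            from .embedding import DEFAULT_PERPLEXITY, embed, extract_activations, plot_embedding

            act = extract_activations(model, X)
            perp = cfg.perplexity or min(DEFAULT_PERPLEXITY.get(cfg.factor, 30.0),
                                         (len(calls) - 1) / 4)
            emb = embed(act, perplexity=perp, rng_seed=cfg.seed,
                        valence=meta["valence"].to_numpy(),
                        context=meta["context"].to_numpy())
            emb.to_frame(meta["call_id"]).to_csv(outdir / "embedding.csv", index=False)
            plot_embedding(emb, color_by=cfg.factor, path=outdir / "embedding.png")
            report["stages"]["embedding"] = {"perplexity": perp, "seed": cfg.seed}

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
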