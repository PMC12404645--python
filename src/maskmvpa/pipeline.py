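"""End-to-end pipeline: simulate -> preprocess -> decode -> RSA -> stats.

``run_pipeline`` executes the configured stages in order, writes every
result as an inspectable text/HDF5 artifact, and records a manifest
(seed, package version, parameter echo) alongside the outputs.  A stage
failure aborts with the stage name while preserving the artifacts of
completed stages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, stage_rng
from .containers import save_epochs
from .decoding import decode_timecourse
from .preprocess import baseline_correct, mnn_whiten
from .rsa import noise_ceiling, rdm_correlate
from .stats import cluster_inference
from .synthetic import make_model_rdms, simulate_eeg_dataset

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(
            f"pipeline stage {stage!r} failed: {cause} "
            "(outputs of completed stages are preserved)"
        )
        self.stage = stage


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the configured stages; returns a result bundle of arrays/paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    manifest = {
        "seed": config.seed,
        "version": __version__,
        "stages": list(config.stages),
        "parameters": _jsonable(config.to_dict()),
    }

    subjects = None
    stage = "simulate"
    try:
        if "simulate" in config.stages:
            rng = stage_rng(config.seed, "simulate")
            subjects = simulate_eeg_dataset(config.design, config.truth, rng)
            for i, subj in enumerate(subjects):
                save_epochs(outdir / f"sub-{i:02d}_epochs.h5", subj)
            bundle["n_subjects"] = len(subjects)

        stage = "preprocess"
        if "preprocess" in config.stages and subjects is not None:
            subjects = [
                mnn_whiten(baseline_correct(s, config.params.baseline_window))
                for s in subjects
            ]

        stage = "decode"
        if "decode" in config.stages and subjects is not None:
            rng = stage_rng(config.seed, "decode")
            results = {}
            for scheme in config.params.schemes:
                per_subj = [
                    decode_timecourse(
                        s, scheme, n_reps=config.params.n_reps, rng=rng,
                        n_bins=config.params.n_bins,
                    )
                    for s in subjects
                ]
                curves = np.stack([r.grand_average() for r in per_subj])
                results[scheme] = {
                    "timecourses": curves,
                    "matrices": np.stack([r.matrices for r in per_subj]),
                }
                df = pd.DataFrame(
                    curves.T,
                    index=pd.Index(subjects[0].time_ms, name="time_ms"),
                    columns=[f"sub{i:02d}" for i in range(len(subjects))],
                )
                df.to_csv(outdir / f"decode_{scheme}_timecourses.tsv", sep="\t")
            bundle["decode"] = results

        stage = "rsa"
        if "rsa" in config.stages and "decode" in bundle:
            rng = stage_rng(config.seed, "rsa")
            model = make_model_rdms(
                config.params.n_model_layers, rng, n_items=config.design.n_objects
            )
            scheme = config.params.schemes[0]
            mats = bundle["decode"][scheme]["matrices"]  # (S, T, K, K)
            peak_t = int(np.argmax(bundle["decode"][scheme]["timecourses"]
                                   .mean(axis=0)))
            layer_corr = np.array(
                [
                    [rdm_correlate(mats[s, peak_t], model.rdms[layer])
                     for layer in range(model.n_layers)]
                    for s in range(mats.shape[0])
                ]
            )
            ceiling = noise_ceiling(mats[:, peak_t])
            bundle["rsa"] = {
                "layer_correlations": layer_corr,
                "noise_ceiling": (ceiling.lower, ceiling.upper),
                "peak_time_ms": float(subjects[0].time_ms[peak_t]),
            }
            pd.DataFrame(
                layer_corr,
                columns=[f"layer{l + 1}" for l in range(model.n_layers)],
            ).to_csv(outdir / "rsa_layer_correlations.tsv", sep="\t",
                     index_label="subject")

        stage = "stats"
        if "stats" in config.stages and "decode" in bundle:
            rng = stage_rng(config.seed, "stats")
            rows = []
            stats_out = {}
            for scheme, res in bundle["decode"].items():
                effect = res["timecourses"] - 50.0
                result = cluster_inference(
                    effect,
                    cdt=config.params.cdt,
                    alpha=config.params.alpha,
                    n_perm=config.params.n_perm,
                    rng=rng,
                )
                stats_out[scheme] = result
                for t, (stat, p, sig) in enumerate(
                    zip(result.stat_map, result.point_p, result.sig_mask)
                ):
                    rows.append(
                        {
                            "scheme": scheme,
                            "time_ms": subjects[0].time_ms[t],
                            "stat": stat,
                            "p": p,
                            "cluster_id": int(result.cluster_labels[t]),
                            "significant": bool(sig),
                        }
                    )
            pd.DataFrame(rows).to_csv(outdir / "stats_clusters.tsv", sep="\t",
                                      index=False)
            bundle["stats"] = stats_out
    except Exception as err:  # annotate with the failing stage
        raise StageError(stage, err) from err

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
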