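"""End-to-end pipeline: phantom simulation through group statistics.

The pipeline chains the functional branch (simulate cohort -> concatenate
-> group ICA -> noise screen -> edge correlations -> RSN clustering ->
group comparison -> seed map) and/or the structural branch (simulate DWI
-> tensor fit -> probabilistic tracking -> connectome -> graph metrics)
from a single YAML config, logging every stage's parameters and writing a
machine-readable JSON report with checksums of all outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import graphs, io, networks, phantoms, tract
from .ica import classify_noise, concatenate_temporal, group_ica
from .image import ellipsoid_mask

logger = logging.getLogger("mconn")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str | Path, out_dir=None) -> dict:
    """Execute the configured stages; returns the JSON-serializable report."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir if out_dir is not None else config.get("out_dir", "mconn_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed, "stages": {}, "outputs": {}}

    if "functional" in config:
        _run_functional(config["functional"], seed, out, report)
    if "structural" in config:
        _run_structural(config["structural"], seed, out, report)

    report["outputs"] = {
        name: _sha256(out / name)
        for name in sorted(report["outputs"])
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _stage(report: dict, name: str, params: dict) -> None:
    logger.info("stage %s: %s", name, params)
    report["stages"][name] = params


def _run_functional(cfg: dict, seed: int, out: Path, report: dict) -> None:
    try:
        ph = dict(cfg.get("phantom", {}))
        if "grid_shape" in ph:
            ph["grid_shape"] = tuple(ph["grid_shape"])
        spec = phantoms.default_functional_spec(seed=seed, **ph)
        hypo_cfg = cfg.get("hypo", {"cluster": 1, "w": 0.3})
        spec_hypo = phantoms.lowered_loading_spec(
            spec, int(hypo_cfg.get("cluster", 1)), float(hypo_cfg.get("w", 0.3))
        )
        n_per_group = int(cfg.get("n_per_group", 4))
        _stage(report, "simulate_cohort",
               {"n_per_group": n_per_group, "w_sham": spec.cluster_loading,
                "hypo": hypo_cfg, "grid_shape": list(spec.grid_shape),
                "n_timepoints": spec.n_timepoints})
        subjects, truth = phantoms.simulate_cohort(spec, spec_hypo, n_per_group, seed)
        images = [img for img, _ in subjects]
        groups = [g for _, g in subjects]
        mask = ellipsoid_mask(spec.grid_shape)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("simulate_cohort", exc) from exc

    try:
        ica_cfg = cfg.get("ica", {})
        n_comp = ica_cfg.get("n_components")
        _stage(report, "group_ica", {"n_components": n_comp})
        concat = concatenate_temporal(images, mask)
        cs = group_ica(concat, n_components=n_comp, seed=seed)
        flags, diag = classify_noise(cs, mask)
        _stage(report, "classify_noise",
               {"n_flagged": int(flags.sum()), "n_retained": int((~flags).sum())})
        retained = cs.retained()
        io.write_timecourses_tsv(
            out / "group_timecourses.tsv",
            np.vstack(retained.timecourses),
            [f"comp{k}" for k in range(retained.n_components)],
        )
        report["outputs"]["group_timecourses.tsv"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("group_ica", exc) from exc

    try:
        zs = networks.subject_z_matrices(retained.timecourses)
        r_group = np.tanh(zs.mean(axis=0))
        np.fill_diagonal(r_group, 1.0)
        zm = networks.zmatrix_from_r(r_group)
        io.write_matrix_tsv(out / "group_z.tsv", zm.z)
        report["outputs"]["group_z.tsv"] = None
        k = int(cfg.get("cluster_k", 4))
        assign = networks.cluster_components(zm, k)
        _stage(report, "cluster_components", {"k": k})
        report["cluster_assignment"] = assign.labels.tolist()
        np.savetxt(out / "clusters.tsv",
                   np.column_stack([np.arange(len(assign.labels)), assign.labels]),
                   fmt="%d", delimiter="\t", header="component\tcluster", comments="")
        report["outputs"]["clusters.tsv"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("cluster_components", exc) from exc

    try:
        cmp_cfg = cfg.get("compare", {})
        alpha = float(cmp_cfg.get("alpha", 0.05))
        method = str(cmp_cfg.get("test", "t"))
        diff = networks.group_difference_matrix(zs, groups, alpha=alpha, method=method)
        _stage(report, "group_difference",
               {"alpha": alpha, "test": method, "n_rejected": len(diff.rejected)})
        report["rejected_edges"] = sorted(list(e) for e in diff.rejected)
        io.write_matrix_tsv(out / "delta_z.tsv", diff.delta_z)
        report["outputs"]["delta_z.tsv"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("group_difference", exc) from exc

    try:
        sm_cfg = cfg.get("seedmap", {"component": 0})
        comp = int(sm_cfg.get("component", 0))
        tm = truth.true_maps[comp]
        seed_mask = (tm > 0.5 * tm.max()) & mask
        zmap = networks.seed_correlation_map(images, seed_mask, mask, concatenate=True)
        _stage(report, "seed_correlation_map", {"component": comp, "concatenate": True})
        io.write_nifti(out / "seed_zmap.nii.gz", zmap)
        report["outputs"]["seed_zmap.nii.gz"] = None
        report["seedmap_max_z"] = float(np.max(zmap))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("seed_correlation_map", exc) from exc


def _run_structural(cfg: dict, seed: int, out: Path, report: dict) -> None:
    try:
        ph = dict(cfg.get("phantom", {}))
        if "grid_shape" in ph:
            ph["grid_shape"] = tuple(ph["grid_shape"])
        bundles = ph.pop("bundles", None)
        if bundles is not None:
            spec = phantoms.DiffusionPhantomSpec(
                bundles=[
                    phantoms.BundleSpec(
                        geometry=b.get("geometry", "straight"),
                        start=tuple(b["start"]),
                        end=tuple(b["end"]),
                        radius=float(b.get("radius", 2.0)),
                        axial_diffusivity=float(b.get("axial_diffusivity", 1.7e-3)),
                        radial_diffusivity=float(b.get("radial_diffusivity", 0.3e-3)),
                    )
                    for b in bundles
                ],
                seed=seed,
                **ph,
            )
        else:
            spec = phantoms.default_diffusion_spec(seed=seed, **ph)
        _stage(report, "simulate_dwi",
               {"grid_shape": list(spec.grid_shape), "noise_sigma": spec.noise_sigma})
        dwi, true_tensors, truth = phantoms.simulate_dwi(spec)
    except Exception as exc:
        raise PipelineError("simulate_dwi", exc) from exc

    try:
        tf = tract.fit_tensor(dwi)
        _stage(report, "fit_tensor", {"n_clamped": tf.n_clamped})
        report["fa_summary"] = {
            "bundle_mean_fa": float(tf.fa[truth.bundle_masks.any(axis=0)].mean()),
            "background_mean_fa": float(tf.fa[~truth.bundle_masks.any(axis=0)].mean()),
        }
        io.write_nifti(out / "fa.nii.gz", tf.fa)
        report["outputs"]["fa.nii.gz"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("fit_tensor", exc) from exc

    try:
        tr_cfg = cfg.get("tracking", {})
        params = tract.TrackingParams(
            **{k: v for k, v in tr_cfg.items()
               if k in tract.TrackingParams.__dataclass_fields__}
        )
        seeds = truth.bundle_masks.any(axis=0) & (tf.fa >= params.fa_stop)
        sl = tract.track_probabilistic(tf, seeds, params, seed=seed)
        _stage(report, "track_probabilistic",
               {"n_streamlines": len(sl), "params": tr_cfg})
        io.write_streamlines_text(out / "streamlines.txt", sl.streamlines)
        report["outputs"]["streamlines.txt"] = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("track_probabilistic", exc) from exc

    try:
        conn = tract.build_connectome(sl, truth.endpoint_labels)
        io.write_matrix_tsv(out / "connectome.tsv", conn.weights,
                            ids=[str(r) for r in conn.region_ids])
        report["outputs"]["connectome.tsv"] = None
        density = float(cfg.get("metrics", {}).get("density", 0.2))
        g = graphs.proportional_threshold(conn.weights, density)
        metrics = {
            "global_efficiency": graphs.global_efficiency(g),
            "transitivity": graphs.transitivity(g) if g.n >= 3 else None,
            "degree": graphs.degree(g).tolist(),
            "density": g.density,
        }
        _stage(report, "graph_metrics", {"density": density})
        report["connectome_metrics"] = metrics
        report["connectome_total_streamlines"] = int(conn.counts.sum() // 2)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("graph_metrics", exc) from exc
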