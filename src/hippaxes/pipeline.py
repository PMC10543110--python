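"""End-to-end synthetic pipeline: simulate -> fit -> axes -> surface -> stats.

Runs the full analysis on synthetic data from a single config: NODDI/DTI
fitting of simulated multi-shell signals, Laplace axis fields and cosine
similarities, midthickness sampling and group averaging, spin-tested map
correlations, subfield classification and OPNNMF parcellation with
stability.  All randomness flows from one root seed expanded per stage;
every stage writes its artifacts plus a JSON manifest with parameters,
seeds, per-stage timings and output hashes, so a rerun with the same config
is bit-identical on the hashed outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .acquisition import multishell_scheme
from .classify import MICRO_FEATURES, evaluate, split_subjects, train_classifier
from .laplace import gradient_fields, solve_all_axes
from .noddi import fit_dti, fit_noddi_volume
from .opnnmf import normalize_metrics, opnnmf_fit, stability_analysis, zscore_weights
from .orientation import similarity_volumes
from .spatial_stats import all_pairs_report, report_matrix
from .surface import average_maps, sample_to_midthickness, subfield_average
from .synthetic import (
    make_ground_truth,
    make_smooth_volume,
    make_synthetic_surface,
    make_voxel_domain,
    simulate_dwi,
)

__all__ = ["PipelineConfig", "run_pipeline", "MissingArtifactError"]

logger = logging.getLogger("hippaxes.pipeline")

STAGES = ("simulate", "fit", "cosine", "surface", "spin", "classify", "opnnmf")

#: metrics sampled onto the surface for the synthetic run
SAMPLED_METRICS = ("ndi", "odi", "fa", "md", "t1w_t2w", "cs_ap", "cs_pd", "cs_io")


class MissingArtifactError(RuntimeError):
    """An enabled stage needs an artifact a disabled stage did not produce."""


@dataclass
class PipelineConfig:
    """Single source of truth for a pipeline run."""

    out_dir: str = "hippaxes_out"
    seed: int = 0
    n_subjects: int = 8
    grid_shape: tuple = (32, 16)
    volume_shape: tuple = (10, 8, 8)
    geometry: str = "slab"
    snr: float = 30.0
    noise_model: str = "gaussian"
    shells: tuple = (1000.0, 2000.0, 3000.0)
    n_dirs: int = 30
    n_b0: int = 6
    n_perm: int = 500
    k: int = 4
    k_range: tuple = (2, 6)
    n_splits: int = 2
    train_fraction: float = 0.7
    thickness_gradient: float = 0.5
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self):
        self.grid_shape = tuple(int(x) for x in self.grid_shape)
        self.volume_shape = tuple(int(x) for x in self.volume_shape)
        self.k_range = tuple(int(x) for x in self.k_range)
        stages = {s: True for s in STAGES}
        stages.update(self.stages or {})
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        self.stages = stages

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["volume_shape"] = list(self.volume_shape)
        d["k_range"] = list(self.k_range)
        d["shells"] = list(self.shells)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(root: int, stage: str) -> int:
    h = hashlib.blake2b(stage.encode(), digest_size=4).digest()
    return (root * 0x9E3779B1 + int.from_bytes(h, "little")) % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages in order; returns the output directory.

    Stage dependencies are explicit: a disabled upstream stage aborts any
    enabled stage that needs its (in-memory) artifacts, naming the missing
    stage.  Stage results live under out_dir/<stage>/ and the manifest at
    out_dir/manifest.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    manifest = {
        "package": "hippaxes",
        "config": config.to_dict(),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in STAGES},
        "timings_s": {},
        "outputs": {},
    }
    art: dict = {}
    scheme = multishell_scheme(config.shells, n_dirs=config.n_dirs, n_b0=config.n_b0)
    subjects = [f"sub-{i:03d}" for i in range(config.n_subjects)]
    hashed_files: list[Path] = []

    def require(stage, *keys):
        for key in keys:
            if key not in art:
                raise MissingArtifactError(
                    f"stage '{stage}' requires artifact '{key}' from a disabled "
                    "upstream stage"
                )

    def timed(stage):
        class _T:
            def __enter__(self_):
                logger.info("stage %s: start", stage)
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, *exc):
                manifest["timings_s"][stage] = round(time.perf_counter() - self_.t0, 3)
                logger.info(
                    "stage %s: done in %.2fs", stage, manifest["timings_s"][stage]
                )

        return _T()

    # ---- simulate: domain, axis fields, ground truth, noisy DWI ----------
    if config.stages["simulate"]:
        with timed("simulate"):
            sdir = out / "simulate"
            sdir.mkdir(exist_ok=True)
            seed = _stage_seed(config.seed, "simulate")
            domain = make_voxel_domain(config.volume_shape, config.geometry, seed)
            coords = solve_all_axes(domain)
            axes = gradient_fields(coords)
            art.update(domain=domain, coords=coords, axes=axes, scheme=scheme)
            scheme.save(sdir / "scheme.bval", sdir / "scheme.bvec")
            for ax in ("AP", "PD", "IO"):
                hio.save_nifti(sdir / f"psi_{ax}.nii.gz", np.nan_to_num(coords.psi(ax)))
            ss = np.random.SeedSequence([seed, 1])
            truth, dwi = {}, {}
            base_mix = (
                0.6 * np.nan_to_num(axes.G_AP)
                + 0.3 * np.nan_to_num(axes.G_PD)
                + 0.15 * np.nan_to_num(axes.G_IO)
            )
            for sub, child in zip(subjects, ss.spawn(config.n_subjects)):
                sub_seed = int(child.generate_state(1)[0] % 2**31)
                rng = np.random.default_rng(sub_seed)
                jitter = rng.normal(0.0, 0.25, base_mix.shape)
                truth[sub] = make_ground_truth(
                    domain, seed=sub_seed, mu_field=base_mix + jitter
                )
                dwi[sub] = simulate_dwi(
                    truth[sub],
                    scheme,
                    snr=config.snr,
                    noise_model=config.noise_model,
                    seed=sub_seed,
                )
            art.update(truth=truth, dwi=dwi)

    # ---- fit: NODDI + DTI maps per subject --------------------------------
    if config.stages["fit"]:
        require("fit", "dwi", "domain")
        with timed("fit"):
            fdir = out / "fit"
            fdir.mkdir(exist_ok=True)
            domain = art["domain"]
            fits = {}
            for sub in subjects:
                maps = fit_noddi_volume(art["dwi"][sub], domain.mask, scheme)
                fa = np.full(domain.mask.shape, np.nan)
                md = np.full(domain.mask.shape, np.nan)
                for idx in zip(*np.nonzero(domain.mask)):
                    tf = fit_dti(art["dwi"][sub][idx], scheme)
                    fa[idx], md[idx] = tf.fa, tf.md
                maps["dti_fa"], maps["dti_md"] = fa, md
                fits[sub] = maps
            art["fits"] = fits
            for name in ("noddi_ndi", "noddi_odi", "dti_fa", "dti_md"):
                hio.save_nifti(
                    fdir / f"{subjects[0]}_{name}.nii.gz",
                    np.nan_to_num(fits[subjects[0]][name]),
                )

    # ---- cosine: similarity volumes --------------------------------------
    if config.stages["cosine"]:
        require("cosine", "fits", "axes")
        with timed("cosine"):
            cdir = out / "cosine"
            cdir.mkdir(exist_ok=True)
            cos = {}
            for sub in subjects:
                cos[sub] = similarity_volumes(
                    art["fits"][sub]["noddi_mu"],
                    art["axes"],
                    mu_valid=art["fits"][sub]["valid"],
                )
            art["cosine"] = cos
            first = cos[subjects[0]]
            for ax in ("AP", "PD", "IO"):
                hio.save_nifti(
                    cdir / f"{subjects[0]}_cs_{ax}.nii.gz", np.nan_to_num(first.cs(ax))
                )

    # ---- surface: sampling and group averaging ---------------------------
    if config.stages["surface"]:
        require("surface", "fits", "cosine", "domain")
        with timed("surface"):
            gdir = out / "surface"
            gdir.mkdir(exist_ok=True)
            seed = _stage_seed(config.seed, "surface")
            surface = make_synthetic_surface(
                config.volume_shape,
                config.grid_shape,
                thickness_gradient=config.thickness_gradient,
            )
            art["surface"] = surface
            subject_maps: dict = {m: [] for m in SAMPLED_METRICS}
            volmap = {
                "ndi": "noddi_ndi",
                "odi": "noddi_odi",
                "fa": "dti_fa",
                "md": "dti_md",
            }
            for i, sub in enumerate(subjects):
                vols = {
                    "ndi": art["fits"][sub]["noddi_ndi"],
                    "odi": art["fits"][sub]["noddi_odi"],
                    "fa": art["fits"][sub]["dti_fa"],
                    "md": art["fits"][sub]["dti_md"],
                    "t1w_t2w": make_smooth_volume(
                        config.volume_shape, seed=seed + 7 * i
                    ),
                    "cs_ap": art["cosine"][sub].cs_AP,
                    "cs_pd": art["cosine"][sub].cs_PD,
                    "cs_io": art["cosine"][sub].cs_IO,
                }
                for metric, vol in vols.items():
                    subject_maps[metric].append(
                        sample_to_midthickness(
                            np.nan_to_num(vol),
                            surface,
                            metric_name=metric,
                            subject_id=sub,
                        )
                    )
            art["subject_maps"] = subject_maps
            means = {}
            for metric, maps in subject_maps.items():
                mean_map, sd_map, count = average_maps(maps)
                means[metric] = mean_map
                hio.save_map_csv(gdir / f"mean_{metric}.csv", mean_map)
                hio.save_map_csv(gdir / f"sd_{metric}.csv", sd_map)
            art["mean_maps"] = means
            hio.save_surface_gifti(gdir / "midthickness.surf.gii", surface)
            hashed_files += sorted(gdir.glob("mean_*.csv"))

    # ---- spin: correlations with torus spin test -------------------------
    if config.stages["spin"] or config.stages["surface"]:
        require("spin", "mean_maps")
    if "mean_maps" in art:
        with timed("spin"):
            pdir = out / "spin"
            pdir.mkdir(exist_ok=True)
            report = all_pairs_report(
                list(art["mean_maps"].values()),
                n_perm=config.n_perm,
                seed=_stage_seed(config.seed, "spin"),
                run_spin=config.stages["spin"],
            )
            report.to_csv(pdir / "correlations.csv", index=False)
            report_matrix(report).to_csv(pdir / "correlation_matrix.csv")
            art["spin_report"] = report
            hashed_files.append(pdir / "correlations.csv")

    # ---- classify: subfield separability ---------------------------------
    if config.stages["classify"]:
        require("classify", "subject_maps", "surface")
        with timed("classify"):
            ldir = out / "classify"
            ldir.mkdir(exist_ok=True)
            labels = art["surface"].subfield_label
            rows = []
            for metric in MICRO_FEATURES:
                for m in art["subject_maps"][metric]:
                    for sf, val in subfield_average(m, labels).items():
                        rows.append(
                            {
                                "subject": m.subject_id,
                                "hemisphere": m.hemisphere,
                                "subfield": sf,
                                "metric": metric,
                                "value": val,
                            }
                        )
            table = (
                pd.DataFrame(rows)
                .pivot_table(
                    index=["subject", "hemisphere", "subfield"],
                    columns="metric",
                    values="value",
                )
                .reset_index()
            )
            table.to_csv(ldir / "subfield_table.csv", index=False)
            n_train = max(2, int(round(config.train_fraction * config.n_subjects)))
            n_test = config.n_subjects - n_train
            train, test = split_subjects(
                table, n_train, n_test, seed=_stage_seed(config.seed, "classify")
            )
            model = train_classifier(train)
            rep = evaluate(model, test, n_train=len(train))
            rep.scores.to_csv(ldir / "f1_scores.csv", index=False)
            (ldir / "report.json").write_text(json.dumps(rep.to_json_dict(), indent=2))
            art["classifier_report"] = rep
            hashed_files += [ldir / "f1_scores.csv", ldir / "subfield_table.csv"]

    # ---- opnnmf: parcellation + stability --------------------------------
    if config.stages["opnnmf"]:
        require("opnnmf", "subject_maps")
        with timed("opnnmf"):
            ndir = out / "opnnmf"
            ndir.mkdir(exist_ok=True)
            metrics = list(SAMPLED_METRICS)
            raw_cols = []
            col_meta = []
            for sub in subjects:
                for metric in metrics:
                    m = next(
                        x for x in art["subject_maps"][metric] if x.subject_id == sub
                    )
                    raw_cols.append(np.nan_to_num(m.values))
                    col_meta.append(
                        {"subject": sub, "metric": metric, "hemisphere": m.hemisphere}
                    )
            raw = np.column_stack(raw_cols)
            stack = normalize_metrics(raw, pd.DataFrame(col_meta))
            fit = opnnmf_fit(stack.X, config.k)
            pd.DataFrame(fit.C).to_csv(ndir / "components.csv", index=False)
            pd.DataFrame(zscore_weights(fit.W)).to_csv(ndir / "weights_z.csv", index=False)
            pd.DataFrame({"vertex": np.arange(len(fit.labels)), "label": fit.labels}).to_csv(
                ndir / "labels.csv", index=False
            )
            k_lo, k_hi = config.k_range
            stab = stability_analysis(
                stack,
                k_range=range(k_lo, k_hi + 1),
                n_splits=config.n_splits,
                seed=_stage_seed(config.seed, "opnnmf"),
            )
            stab.table.to_csv(ndir / "stability.csv", index=False)
            art["opnnmf_fit"] = fit
            art["stability"] = stab
            hashed_files += [ndir / "labels.csv", ndir / "stability.csv"]

    manifest["outputs"] = {
        str(p.relative_to(out)): _sha256(p) for p in hashed_files if p.exists()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.removeHandler(handler)
    handler.close()
    return out
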