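"""Config-driven end-to-end runs: mirror -> align -> model -> statistics.

Two entry points mirror the two halves of the analysis:

* :func:`run_separate_groups_analysis` keeps left and right as two groups
  and runs the location / variance–covariance scale / orientation
  permutation tests, emitting a table of D-statistics and permutation
  p-values.
* :func:`run_pooled_analysis` pools both sides, fits the PCA shape model,
  retains modes by parallel analysis, screens per-mode normality, compares
  sexes with an age-adjusted ANCOVA under a Bonferroni family threshold,
  and estimates per-mode ICC(2,1).

All randomness flows from one top-level seed through named stage seeds, so
repeated runs produce byte-identical JSON reports.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alignment import (AlignedDataset, RegistrationConfig,
                        correspond_to_reference, groupwise_align,
                        mirror_sample)
from .asymmetry_tests import permutation_test
from .pooled_stats import ancova_table, icc_2_1, ks_normality
from .shape_io import ShapeSample, read_sample_sheet, read_shape, write_shape
from .shape_model import (fit_pca, parallel_analysis,
                          point_to_surface_distance, reconstruct_at_sd)
from .syn_shapes import SyntheticConfig, generate_population

__all__ = ["RunConfig", "ConfigError", "load_config",
           "run_separate_groups_analysis", "run_pooled_analysis"]

logger = logging.getLogger("shapesym")

_STAGES = ("synthetic", "pa_left", "pa_right", "perm_location", "perm_scale",
           "perm_orientation", "pa_pooled", "reference_subsample")


class ConfigError(ValueError):
    """Invalid run configuration (CLI maps this to exit code 2)."""


@dataclasses.dataclass
class RunConfig:
    mode: str = "synthetic"                  # 'synthetic' or 'real'
    synthetic: Optional[SyntheticConfig] = None
    input_dir: Optional[str] = None          # real mode: geometry + samples.csv
    input_format: Optional[str] = None
    reference_sample_id: Optional[str] = None
    registration: RegistrationConfig = dataclasses.field(
        default_factory=RegistrationConfig)
    n_perm: int = 10_000
    scheme: str = "side_swap"
    pa_n_sim: int = 100
    pa_criterion: str = "mean"
    alpha_family: float = 0.05
    conf_level: float = 0.95
    seed: int = 0
    out_dir: str = "shapesym_out"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigError(f"mode must be 'synthetic' or 'real', got {self.mode!r}")
        if self.mode == "synthetic" and self.input_dir is not None:
            raise ConfigError("specify either synthetic parameters or input "
                              "paths, not both")
        if self.mode == "real" and self.input_dir is None:
            raise ConfigError("real mode requires input_dir")
        if self.n_perm < 100:
            raise ConfigError(f"n_perm must be >= 100, got {self.n_perm}")
        if self.scheme not in ("side_swap", "free"):
            raise ConfigError("scheme must be 'side_swap' or 'free'")
        if self.pa_criterion not in ("mean", "percentile95"):
            raise ConfigError("pa_criterion must be 'mean' or 'percentile95'")
        if not 0 < self.alpha_family < 1 or not 0 < self.conf_level < 1:
            raise ConfigError("alpha_family and conf_level must lie in (0, 1)")
        if self.mode == "synthetic" and self.synthetic is None:
            self.synthetic = default_synthetic_config(self.seed)

    def stage_seed(self, stage: str) -> int:
        return int(np.random.SeedSequence([self.seed, _STAGES.index(stage)])
                   .generate_state(1)[0])

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        out["synthetic"] = self.synthetic.to_dict() if self.synthetic else None
        out["registration"] = dataclasses.asdict(self.registration)
        return out


def default_synthetic_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_subjects=30, n_points=100, n_modes_true=4,
        eigenvalues_true=(9.0, 4.0, 2.0, 1.0),
        icc_per_mode=(0.9, 0.7, 0.5, 0.3),
        noise_sd=0.05, rotation_max_deg=20.0, translation_max_mm=10.0,
        scale_range=(0.9, 1.1), seed=seed)


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML/JSON file plus keyword overrides."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    synthetic = raw.pop("synthetic", None)
    registration = raw.pop("registration", None)
    try:
        if isinstance(synthetic, dict):
            for tup in ("age_range", "scale_range"):
                if tup in synthetic:
                    synthetic[tup] = tuple(synthetic[tup])
            synthetic = SyntheticConfig(**synthetic)
        if isinstance(registration, dict):
            registration = RegistrationConfig(**registration)
        kwargs = dict(raw)
        if synthetic is not None:
            kwargs["synthetic"] = synthetic
        if registration is not None:
            kwargs["registration"] = registration
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# data preparation


def _mesh_area(sample: ShapeSample) -> float:
    a = sample.points[sample.faces[:, 0]]
    b = sample.points[sample.faces[:, 1]]
    c = sample.points[sample.faces[:, 2]]
    return float(np.linalg.norm(np.cross(b - a, c - a), axis=1).sum() / 2)


def _subsample_surface(sample: ShapeSample, n: int, seed: int) -> np.ndarray:
    """Deterministic area-weighted point sampling on a triangulated surface."""
    rng = np.random.default_rng(seed)
    a = sample.points[sample.faces[:, 0]]
    b = sample.points[sample.faces[:, 1]]
    c = sample.points[sample.faces[:, 2]]
    areas = np.linalg.norm(np.cross(b - a, c - a), axis=1) / 2
    tri = rng.choice(len(areas), size=n, p=areas / areas.sum())
    u, v = rng.random(n), rng.random(n)
    flip = u + v > 1
    u[flip], v[flip] = 1 - u[flip], 1 - v[flip]
    w = 1 - u - v
    return (w[:, None] * a[tri] + u[:, None] * b[tri] + v[:, None] * c[tri])


def _load_samples(config: RunConfig) -> List[ShapeSample]:
    if config.mode == "synthetic":
        cfg = dataclasses.replace(config.synthetic,
                                  seed=config.stage_seed("synthetic"))
        pairs, _ = generate_population(cfg)
        return [s for pair in pairs for s in pair]

    indir = Path(config.input_dir)
    sheet = read_sample_sheet(indir / "samples.csv")
    samples = []
    for row in sheet.itertuples():
        matches = sorted(indir.glob(f"{row.sample_id}.*"))
        if not matches:
            raise ConfigError(f"no geometry file for sample {row.sample_id} "
                              f"in {indir}")
        geom = read_shape(matches[0], format=config.input_format)
        samples.append(geom.with_geometry(
            geom.points, faces=geom.faces, sample_id=row.sample_id,
            subject_id=row.subject_id, side=row.side, sex=row.sex,
            age=None if pd.isna(row.age) else float(row.age)))
    if any(s.faces is not None for s in samples):
        samples = _correspond_all(samples, config)
    return samples


def _correspond_all(samples: List[ShapeSample], config: RunConfig):
    """Closest-point correspondence of meshes against a reference cloud.

    The reference is a seeded area-weighted subsample of the chosen (or
    first) sample's surface; the target point count follows the
    0.7-points-per-mm² density rule.
    """
    ref_id = config.reference_sample_id or samples[0].sample_id
    ref = next((s for s in samples if s.sample_id == ref_id), None)
    if ref is None or ref.faces is None:
        raise ConfigError(f"reference sample {ref_id!r} not found or has no faces")
    mean_area = float(np.mean([_mesh_area(s) for s in samples
                               if s.faces is not None]))
    n_ref = max(10, int(round(0.7 * mean_area)))
    cloud = _subsample_surface(ref, n_ref,
                               config.stage_seed("reference_subsample"))
    logger.info("correspondence: %d reference points (0.7 x %.1f mm^2)",
                n_ref, mean_area)
    return [correspond_to_reference(s, cloud) if s.faces is not None else s
            for s in samples]


def prepare_aligned(config: RunConfig) -> AlignedDataset:
    """Load (or generate), mirror right-side samples, and groupwise align."""
    samples = _load_samples(config)
    logger.info("loaded %d samples", len(samples))
    samples = [mirror_sample(s) if s.side == "R" else s for s in samples]
    aligned = groupwise_align(samples, config.registration)
    logger.info("alignment converged in %d iterations (objective %.3e)",
                aligned.n_iterations, aligned.objective_history[-1])
    return aligned


def _paired_side_matrices(aligned: AlignedDataset):
    """Left and right row matrices ordered so row i of each is subject i."""
    meta = aligned.metadata
    left = meta[meta.side == "L"].sort_values("subject_id")
    right = meta[meta.side == "R"].sort_values("subject_id")
    if not (left.subject_id.values == right.subject_id.values).all():
        raise ConfigError("left/right samples are not paired by subject")
    return (aligned.data[left.index.values], aligned.data[right.index.values],
            left.subject_id.values)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_report(report: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, sort_keys=True, indent=1,
                               default=_json_default))


# ---------------------------------------------------------------------------
# analyses


def run_separate_groups_analysis(config: RunConfig,
                                 aligned: Optional[AlignedDataset] = None) -> dict:
    """Left vs right as two groups: permutation tests on three aspects."""
    outdir = Path(config.out_dir)
    if aligned is None:
        aligned = prepare_aligned(config)
    L, R, _subjects = _paired_side_matrices(aligned)

    pa_l = parallel_analysis(L, n_sim=config.pa_n_sim,
                             criterion=config.pa_criterion,
                             seed=config.stage_seed("pa_left"))
    pa_r = parallel_analysis(R, n_sim=config.pa_n_sim,
                             criterion=config.pa_criterion,
                             seed=config.stage_seed("pa_right"))
    k = max(1, min(pa_l.k_retained, pa_r.k_retained))
    k = min(k, L.shape[0] - 1, R.shape[0] - 1)
    logger.info("parallel analysis: k_left=%d k_right=%d -> k=%d",
                pa_l.k_retained, pa_r.k_retained, k)

    results = {
        "location": permutation_test("location", L, R, n_perm=config.n_perm,
                                     scheme=config.scheme,
                                     seed=config.stage_seed("perm_location")),
        "scale": permutation_test("scale", L, R, n_perm=config.n_perm,
                                  scheme=config.scheme,
                                  seed=config.stage_seed("perm_scale")),
        "orientation": permutation_test("orientation", L, R, k=k,
                                        n_perm=config.n_perm,
                                        scheme=config.scheme,
                                        seed=config.stage_seed("perm_orientation")),
    }

    rows = [{"test": "location", "D_stat": float(results["location"].d_observed),
             "P_perm": float(results["location"].p_perm)},
            {"test": "scale", "D_stat": float(results["scale"].d_observed),
             "P_perm": float(results["scale"].p_perm)}]
    orient = results["orientation"]
    for j in range(k):
        rows.append({"test": f"orientation_{j + 1}",
                     "D_stat": float(orient.d_observed[j]),
                     "P_perm": float(orient.p_perm[j])})
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(outdir / "separate_groups_tests.csv", index=False)

    report = {
        "analysis": "separate_groups",
        "version": __version__,
        "config": config.to_dict(),
        "n_left": int(L.shape[0]), "n_right": int(R.shape[0]),
        "k_retained": {"left": pa_l.k_retained, "right": pa_r.k_retained,
                       "used": k},
        "tests": {name: {
            "d_observed": res.d_observed,
            "p_perm": res.p_perm,
            "n_exceed": res.n_exceed,
            "n_perm": res.n_perm,
            "scheme": res.scheme,
            "d_perm": res.d_perm,
        } for name, res in results.items()},
    }
    _write_report(report, outdir / "separate_groups_report.json")
    return report


def run_pooled_analysis(config: RunConfig,
                        aligned: Optional[AlignedDataset] = None) -> dict:
    """Both sides pooled: shape model, normality, sex ANCOVA and ICC."""
    outdir = Path(config.out_dir)
    if aligned is None:
        aligned = prepare_aligned(config)
    meta = aligned.metadata

    model = fit_pca(aligned)
    pa = parallel_analysis(aligned.data, n_sim=config.pa_n_sim,
                           criterion=config.pa_criterion,
                           seed=config.stage_seed("pa_pooled"))
    k = max(1, min(pa.k_retained, model.n_modes))
    model.k_retained = k
    total_var = float(model.eigenvalues.sum())
    cum_share = float(model.eigenvalues[:k].sum() / total_var)
    logger.info("pooled PCA: %d modes, k_retained=%d (%.0f%% of variance)",
                model.n_modes, k, 100 * cum_share)

    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "rank": np.arange(1, model.n_modes + 1),
        "observed_eigenvalue": model.eigenvalues,
        "simulated_criterion": pa.simulated_criterion[:model.n_modes],
        "retained": np.arange(1, model.n_modes + 1) <= k,
    }).to_csv(outdir / "scree_parallel_analysis.csv", index=False)

    scores = model.scores_sd[:, :k]
    ks = [ks_normality(scores[:, j]) for j in range(k)]

    sexes = meta.sex.values
    ages = np.array([np.nan if a is None else a for a in meta.age.values],
                    dtype=float)
    ancova = ancova_table(scores, sexes, ages, alpha_family=config.alpha_family)
    excluded = ancova.per_mode[0].n_excluded_missing_age
    if excluded:
        logger.warning("ANCOVA excluded %d samples with missing age", excluded)

    left = meta[meta.side == "L"].sort_values("subject_id")
    right = meta[meta.side == "R"].sort_values("subject_id")
    icc = [icc_2_1(scores[left.index.values, j], scores[right.index.values, j],
                   conf_level=config.conf_level) for j in range(k)]

    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{"mode": j + 1, "ks_p": ks[j].p_value,
                   "ancova_p": ancova.per_mode[j].p_value,
                   "significant": (j + 1) in ancova.significant_modes}
                  for j in range(k)]).to_csv(outdir / "sex_ancova.csv", index=False)
    pd.DataFrame([{"mode": j + 1, "icc": icc[j].icc,
                   "ci_low": icc[j].ci_low, "ci_high": icc[j].ci_high,
                   "significantly_symmetric": icc[j].significantly_symmetric}
                  for j in range(k)]).to_csv(outdir / "icc.csv", index=False)

    # +/-3 SD mode reconstructions
    recon_dir = outdir / "reconstructions"
    for j in range(1, k + 1):
        for c in (-3.0, 3.0):
            vec = reconstruct_at_sd(model, j, c)
            tag = "minus3sd" if c < 0 else "plus3sd"
            write_shape(vec.reshape(-1, 3), recon_dir / f"mode{j}_{tag}.csv")

    # distance maps along flagged modes, between the extreme individuals
    maps = {}
    for j in ancova.significant_modes:
        col = scores[:, j - 1]
        lo_i, hi_i = int(np.argmin(col)), int(np.argmax(col))
        dist = point_to_surface_distance(
            aligned.data[lo_i].reshape(-1, 3), aligned.data[hi_i].reshape(-1, 3))
        name = f"mode{j}_extremes_distance.csv"
        pd.DataFrame({"distance_mm": dist}).to_csv(outdir / name, index=False)
        maps[f"mode_{j}"] = {"low": meta.sample_id.values[lo_i],
                             "high": meta.sample_id.values[hi_i],
                             "max_distance_mm": float(dist.max())}

    report = {
        "analysis": "pooled",
        "version": __version__,
        "config": config.to_dict(),
        "n_samples": int(aligned.n_samples),
        "k_retained": k,
        "eigenvalues": model.eigenvalues,
        "cumulative_variance_share": cum_share,
        "ks_p_values": [r.p_value for r in ks],
        "ancova": {
            "p_values": ancova.p_values,
            "alpha_adjusted_exact": ancova.alpha_adjusted_exact,
            "alpha_adjusted_rounded": ancova.alpha_adjusted_rounded,
            "significant_modes": ancova.significant_modes,
            "n_excluded_missing_age": excluded,
        },
        "icc": [{"mode": j + 1, "icc": r.icc, "ci_low": r.ci_low,
                 "ci_high": r.ci_high,
                 "significantly_symmetric": r.significantly_symmetric}
                for j, r in enumerate(icc)],
        "distance_maps": maps,
    }
    _write_report(report, outdir / "pooled_report.json")
    return report
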