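"""Desk-scale orchestration of the whole study.

``run_study`` executes the stages in acquisition order for a synthetic
cohort: generate paired resting runs and task runs per subject, denoise,
derive individualized M1 seed spheres from the task GLM, compute
pre/post connectivity (interhemispheric Fisher-z, seed-averaged IC and
LCOR), run the group tests and optional voxel-wise cluster inference,
solve each subject's phantom electric-field model, and regress
connectivity change on ROI-mean field magnitude.  Everything is a pure
function of the configuration and the master seed; per-stage seeds are
derived by stable seed-sequence hashing, so reports are bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .connectivity import (
    AnalysisMask,
    ICParams,
    KernelSpec,
    interhemispheric_fc,
    intrinsic_connectivity,
    local_correlation,
    roi_mean,
)
from .fem import (
    ConductivityTable,
    MontageSpec,
    efield_to_voxels,
    place_electrodes,
    roi_mean_ef,
    solve_field,
    voxels_to_tetmesh,
)
from .images import RoiSphere, default_affine
from .preprocess import concat_runs, denoise_run, standardize
from .seeds import box_mask, pick_peak_seed, resolve_sphere, run_block_glm
from .stats import (
    cluster_inference,
    paired_t_one_tailed,
    shapiro_wilk_screen,
    simple_regression,
)
from .synthetic import (
    BlockDesign,
    GroundTruth,
    TumorSpec,
    default_truth,
    make_head_phantom,
    make_motion_trace,
    make_rest_bold,
    make_task_bold,
)

_STAGES = {"rest": 1, "task": 2, "motion": 3, "phantom": 4, "perm": 5}


def derive_seed(master_seed: int, stage: str, subject: int = 0) -> int:
    """Stable per-stage seed below 2^31."""
    s = np.random.SeedSequence([int(master_seed), _STAGES.get(stage, 99), subject])
    return int(s.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class StudyConfig:
    """All tunables of the desk-scale study, with the study's defaults
    (64 IC components, 8-mm LCOR kernel, 6-mm seeds, 2-mA C3/FP1 montage)."""

    cohort_size: int = 8
    grid_shape: tuple[int, int, int] = (24, 24, 18)
    voxel_size_mm: float = 4.0
    n_volumes_per_run: int = 75
    n_runs_per_session: int = 2
    tr_seconds: float = 2.0
    base_r: float = 0.5
    delta_r: float = 0.15
    noise_sd: float = 0.2
    drift_amplitude: float = 0.2
    # preprocessing
    n_compcor: int = 5
    z_thresh: float = 5.0
    fd_thresh: float = 0.9
    highpass_hz: float = 0.009
    # seeds / task
    seed_radius_mm: float = 6.0
    task_block_seconds: float = 20.0
    task_n_volumes: int = 60
    glm_smooth_fwhm_mm: float = 6.0
    # connectivity
    ic_components: int = 64
    lcor_fwhm_mm: float = 8.0
    # statistics
    voxel_p_thresh: float = 0.005
    cluster_q_thresh: float = 0.05
    n_perm: int = 500
    # electric field model
    montage: MontageSpec = field(default_factory=MontageSpec)
    conductivities: ConductivityTable = field(default_factory=ConductivityTable)
    phantom_voxel_mm: float = 6.0
    phantom_radii: tuple[float, ...] = (92.0, 85.0, 78.0, 75.0, 67.0)
    # stage switches (voxel-wise clusters and FEM are the slow stages)
    with_task_seeds: bool = True
    with_voxelwise: bool = True
    with_efield: bool = True
    with_maps: bool = True
    master_seed: int = 20201119
    out_dir: str | None = None

    def to_json_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "montage" in d and isinstance(d["montage"], dict):
            d["montage"] = MontageSpec(**d["montage"])
        if "conductivities" in d and isinstance(d["conductivities"], dict):
            d["conductivities"] = ConductivityTable(**d["conductivities"])
        for key in ("grid_shape", "phantom_radii"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_json_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


def _subject_truth(cfg: StudyConfig, subject: int, null: bool = False) -> GroundTruth:
    return default_truth(
        delta_r=0.0 if null else cfg.delta_r,
        base_r=cfg.base_r,
        seed=derive_seed(cfg.master_seed, "rest", subject),
        grid_shape=cfg.grid_shape,
        voxel_size_mm=cfg.voxel_size_mm,
        noise_sd=cfg.noise_sd,
    )


def _noise_border_mask(grid_shape) -> np.ndarray:
    """One-voxel border shell: the stand-in 'noise ROI' for aCompCor."""
    m = np.ones(grid_shape, dtype=bool)
    m[1:-1, 1:-1, 1:-1] = False
    return m


def _session_residual(cfg: StudyConfig, truth: GroundTruth, session: str,
                      subject: int):
    runs = []
    border = _noise_border_mask(cfg.grid_shape)
    for run in range(cfg.n_runs_per_session):
        run_truth = GroundTruth(
            region_centers=truth.region_centers,
            pairwise_r=truth.pairwise_r,
            delta_r=truth.delta_r,
            noise_sd=truth.noise_sd,
            seed=derive_seed(truth.seed, "rest", run),
        )
        bold = make_rest_bold(
            run_truth, cfg.grid_shape, cfg.n_volumes_per_run, cfg.tr_seconds,
            cfg.voxel_size_mm, drift_amplitude=cfg.drift_amplitude,
            session=session,
        )
        motion = make_motion_trace(
            bold.n_volumes,
            seed=derive_seed(cfg.master_seed, "motion", subject * 100 + run),
        )
        resid, _, _ = denoise_run(
            bold, motion, noise_mask=border, n_compcor=cfg.n_compcor,
            z_thresh=cfg.z_thresh, fd_thresh=cfg.fd_thresh,
            highpass_hz=cfg.highpass_hz,
        )
        runs.append(standardize(resid))
    return concat_runs(runs)


def _derive_seeds(cfg: StudyConfig, truth: GroundTruth, subject: int,
                  affine: np.ndarray) -> dict[str, RoiSphere]:
    half = np.array(cfg.grid_shape) * cfg.voxel_size_mm / 2.0
    out = {}
    for side, center, (lo, hi) in (
        ("left", truth.region_centers[0],
         ((-half[0], -half[1], -half[2]), (-cfg.voxel_size_mm, half[1], half[2]))),
        ("right", truth.region_centers[1],
         ((cfg.voxel_size_mm, -half[1], -half[2]), (half[0], half[1], half[2]))),
    ):
        if cfg.with_task_seeds:
            t = GroundTruth(
                region_centers=truth.region_centers,
                pairwise_r=truth.pairwise_r,
                delta_r=0.0,
                activation_center=center,
                activation_amplitude=3.0,
                noise_sd=truth.noise_sd,
                seed=derive_seed(cfg.master_seed, "task",
                                 subject * 10 + (0 if side == "left" else 1)),
            )
            design = BlockDesign(cfg.task_n_volumes, cfg.tr_seconds,
                                 cfg.task_block_seconds)
            task = make_task_bold(t, design, cfg.grid_shape, cfg.voxel_size_mm)
            tmap = run_block_glm(task, design, cfg.glm_smooth_fwhm_mm,
                                 cfg.highpass_hz)
            allowed = box_mask(cfg.grid_shape, affine, lo, hi)
            out[side] = pick_peak_seed(tmap, allowed, cfg.seed_radius_mm,
                                       affine, side=side)
        else:
            vox = resolve_sphere(center, cfg.seed_radius_mm, affine,
                                 cfg.grid_shape)
            out[side] = RoiSphere(center, cfg.seed_radius_mm, vox, side=side)
    return out


def _subject_efield(cfg: StudyConfig, subject: int) -> dict:
    rng = np.random.default_rng(derive_seed(cfg.master_seed, "phantom", subject))
    radii = np.array(cfg.phantom_radii, float)
    radii[1] += rng.uniform(-2.0, 2.0)  # skull outer radius varies by head
    edema = 14.0 + rng.uniform(0.0, 6.0)
    tumor = TumorSpec(
        center_mm=(-28.0, 5.0, 22.0),
        radii_mm={"edema": edema, "tumor_nonenhancing": edema * 0.7,
                  "tumor_enhancing": edema * 0.45, "necrosis": edema * 0.25},
    )
    phantom = make_head_phantom(tuple(radii), tumor, cfg.phantom_voxel_mm)
    mesh = voxels_to_tetmesh(phantom)
    patches = place_electrodes(mesh, cfg.montage)
    sol = solve_field(mesh, cfg.conductivities, patches, cfg.montage.current_A)
    ef = efield_to_voxels(sol, phantom)
    brain = phantom.mask("GM", "WM", "tumor_enhancing", "tumor_nonenhancing",
                         "necrosis", "edema")
    brain_vals = ef[brain]
    gm_r = radii[3]
    m1_center = cfg.montage.direction("anode") * (gm_r - 4.0)
    m1 = RoiSphere(
        m1_center, cfg.seed_radius_mm,
        resolve_sphere(m1_center, cfg.seed_radius_mm, phantom.affine,
                       phantom.data.shape),
        side="left",
    )
    return {
        "mean_brain_ef": float(np.nanmean(brain_vals)),
        "left_m1_ef": roi_mean_ef(ef, m1, restrict_mask=brain),
    }


def run_study(config: StudyConfig) -> dict:
    """Execute the full study; returns the report dict (and writes
    ``report.json`` plus artifacts when ``config.out_dir`` is set)."""
    cfg = config
    if cfg.cohort_size < 2:
        raise StageError("group_stats", "cohort size must be >= 2 for paired tests")
    affine = default_affine(cfg.voxel_size_mm, cfg.grid_shape)
    mask = AnalysisMask(np.ones(cfg.grid_shape, dtype=bool))

    per_subject = []
    ic_pre, ic_post, lcor_pre, lcor_post = [], [], [], []
    for subject in range(cfg.cohort_size):
        try:
            truth = _subject_truth(cfg, subject)
            seeds = _derive_seeds(cfg, truth, subject, affine)
            row: dict = {"subject": subject, "seeds": {
                s: seeds[s].center_mm.tolist() for s in seeds}}
            for session in ("pre", "post"):
                resid = _session_residual(cfg, truth, session, subject)
                row[f"interhemispheric_z_{session}"] = interhemispheric_fc(
                    resid, seeds["left"], seeds["right"])
                if cfg.with_maps:
                    ic = intrinsic_connectivity(
                        resid, mask, ICParams(cfg.ic_components)).normalize()
                    lc = local_correlation(resid, mask,
                                           KernelSpec(cfg.lcor_fwhm_mm))
                    for side in ("left", "right"):
                        row[f"ic_{side}_{session}"] = roi_mean(ic, seeds[side])
                        row[f"lcor_{side}_{session}"] = roi_mean(lc, seeds[side])
                    if session == "pre":
                        ic_pre.append(ic.data), lcor_pre.append(lc.data)
                    else:
                        ic_post.append(ic.data), lcor_post.append(lc.data)
            per_subject.append(row)
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001 - annotate with the stage
            raise StageError(f"subject_{subject}", str(e)) from e

    metrics = ["interhemispheric_z"]
    if cfg.with_maps:
        metrics += ["ic_left", "ic_right", "lcor_left", "lcor_right"]
    group = {}
    for m in metrics:
        pre = np.array([s[f"{m}_pre"] for s in per_subject])
        post = np.array([s[f"{m}_post"] for s in per_subject])
        res = paired_t_one_tailed(pre, post)
        if len(pre) >= 3:
            w, p_norm = shapiro_wilk_screen(post - pre)
        else:  # normality screen undefined below n = 3
            w = p_norm = float("nan")
        group[m] = {**res.as_dict(), "shapiro_w": w, "shapiro_p": p_norm}

    clusters = {}
    if cfg.with_voxelwise and cfg.with_maps:
        for name, pre_s, post_s in (("ic", ic_pre, ic_post),
                                    ("lcor", lcor_pre, lcor_post)):
            diffs = np.stack(post_s) - np.stack(pre_s)
            cres = cluster_inference(
                diffs, mask.data, cfg.voxel_p_thresh, cfg.n_perm,
                seed=derive_seed(cfg.master_seed, "perm",
                                 0 if name == "ic" else 1))
            clusters[name] = {
                "n_clusters": cres.n_clusters,
                "sizes": cres.sizes.tolist(),
                "p_values": cres.p_values.tolist(),
                "q_values": cres.q_values.tolist(),
                "surviving": cres.surviving(cfg.cluster_q_thresh).tolist(),
            }

    efield = {}
    regressions = {}
    if cfg.with_efield:
        ef_rows = [_subject_efield(cfg, s) for s in range(cfg.cohort_size)]
        ef = np.array([r["left_m1_ef"] for r in ef_rows])
        efield = {
            "per_subject_left_m1_ef": ef.tolist(),
            "mean_brain_ef": float(np.mean([r["mean_brain_ef"] for r in ef_rows])),
            "mean_left_m1_ef": float(ef.mean()),
        }
        if cfg.with_maps and cfg.cohort_size >= 3:
            for m in ("ic_left", "ic_right", "lcor_left", "lcor_right"):
                delta = np.array([s[f"{m}_post"] - s[f"{m}_pre"]
                                  for s in per_subject])
                r = simple_regression(ef, delta)
                regressions[m] = r.as_dict()

    report = {
        "per_subject": per_subject,
        "group_tests": group,
        "clusters": clusters,
        "efield": efield,
        "regressions": regressions,
        "provenance": {
            "config_hash": cfg.config_hash(),
            "master_seed": cfg.master_seed,
            "package_version": __version__,
            "config": cfg.to_json_dict(),
        },
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# report schema (shipped alongside; minimal validator, no external deps)

REPORT_SCHEMA = {
    "type": "object",
    "required": ["per_subject", "group_tests", "clusters", "efield",
                 "regressions", "provenance"],
    "properties": {
        "per_subject": {"type": "array"},
        "group_tests": {"type": "object"},
        "clusters": {"type": "object"},
        "efield": {"type": "object"},
        "regressions": {"type": "object"},
        "provenance": {
            "type": "object",
            "required": ["config_hash", "master_seed", "package_version"],
        },
    },
}

_TYPES = {"object": dict, "array": list, "number": (int, float), "string": str}


def validate_report(report: dict, schema: dict | None = None, path: str = "$") -> None:
    """Validate a report against the shipped JSON schema subset
    (type / required / properties); raises ValueError on mismatch."""
    schema = schema if schema is not None else REPORT_SCHEMA
    expected = schema.get("type")
    if expected and not isinstance(report, _TYPES[expected]):
        raise ValueError(f"{path}: expected {expected}")
    if isinstance(report, dict):
        for key in schema.get("required", []):
            if key not in report:
                raise ValueError(f"{path}: missing required key '{key}'")
        for key, sub in schema.get("properties", {}).items():
            if key in report:
                validate_report(report[key], sub, f"{path}.{key}")
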