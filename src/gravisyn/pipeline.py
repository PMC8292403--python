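"""End-to-end orchestration: simulate or ingest cycle matrices, extract
modules per participant and gravity level, cluster within and across gravity
levels, fit the condition tensor, and report similarities with bootstrap
chance levels.

All stage seeds derive deterministically from a single master seed via fixed
offsets (see :data:`STAGE_OFFSETS`), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering, factorization, similarity, synthetic, tensor
from .errors import InvalidArgumentError
from .preprocessing import CycleMatrix, normalize_amplitude, scale_unit_variance

logger = logging.getLogger(__name__)

STAGE_OFFSETS = {
    "simulate": 1000,
    "nmf": 2000,
    "cluster": 3000,
    "tensor": 4000,
    "bootstrap": 5000,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage seed = master seed + fixed documented offset."""
    if stage not in STAGE_OFFSETS:
        raise InvalidArgumentError(f"unknown stage {stage!r}")
    return master_seed + STAGE_OFFSETS[stage]


@dataclass
class AnalysisConfig:
    """Settings for a full analysis run."""

    seed: int = 0
    out_dir: str = "gravisyn_out"
    input_dir: str | None = None  # None -> simulate
    muscles: list[str] = field(default_factory=lambda: list(range(12)))
    gravity_labels: list[str] = field(
        default_factory=lambda: ["1g", "0.6g", "0.38g", "0.16g", "0.07g"]
    )
    speed_labels: list[str] = field(default_factory=list)
    n_bins: int = 200
    n_cycles: int = 10
    # synthetic generator
    n_participants: int = 9
    n_modules_true: int = 4
    profile_kinds: list[str] = field(
        default_factory=lambda: [
            "constant", "linear_decreasing", "threshold_decreasing", "u_shaped",
        ]
    )
    noise_sd: float = 0.02
    participant_sigma: float = 0.1
    # NMF settings
    nmf_restarts: int = 20
    cv_folds: int = 5
    cv_reps: int = 20
    cv_restarts: int = 3
    vaf_threshold: float = 90.0
    n_max: int = 8
    # clustering settings
    k_min: int = 2
    k_max: int = 10
    cluster_inits: int = 20
    # tensor settings
    tensor_components: int | None = None  # None -> use clustering k*
    tensor_restarts: int = 8
    # bootstrap
    n_boot: int = 10_000

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default, sort_keys=True)


def _get_matrices(cfg: AnalysisConfig) -> tuple[dict, synthetic.GroundTruth | None]:
    """Cycle matrices keyed (participant, gravity): simulated, or loaded
    from ``<input_dir>/P<pp>_<gravity>.csv``."""
    if cfg.input_dir is None:
        gt = synthetic.make_ground_truth(
            n_modules=cfg.n_modules_true,
            condition_labels=cfg.gravity_labels,
            profile_kinds=cfg.profile_kinds,
            seed=derive_seed(cfg.seed, "simulate"),
            n_participants=cfg.n_participants,
            noise_sd=cfg.noise_sd,
            participant_sigma=cfg.participant_sigma,
            n_bins=cfg.n_bins,
        )
        return synthetic.generate_condition_set(gt, seed=derive_seed(cfg.seed, "simulate")), gt
    matrices = {}
    for p in range(cfg.n_participants):
        for g in cfg.gravity_labels:
            path = Path(cfg.input_dir) / f"P{p:02d}_{g}.csv"
            if not path.exists():
                raise InvalidArgumentError(f"missing cycle matrix for (P{p:02d}, {g}): {path}")
            matrices[(p, g)] = CycleMatrix.from_csv(path, participant=f"P{p:02d}", condition=g)
    return matrices, None


def run_condition_analysis(cfg: AnalysisConfig) -> dict:
    """Per-gravity module extraction, clustering, and similarity report."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    matrices, gt = _get_matrices(cfg)
    participants = sorted({p for p, _ in matrices})
    logger.info("condition analysis: %d participants x %d gravity levels",
                len(participants), len(cfg.gravity_labels))

    # amplitude normalization across each participant's conditions
    normalized: dict[tuple[int, str], CycleMatrix] = {}
    for p in participants:
        per_cond = {g: matrices[(p, g)] for g in cfg.gravity_labels}
        for g, m in normalize_amplitude(per_cond).items():
            normalized[(p, g)] = m

    # per participant x gravity: module-number selection + extraction
    nmf_seed = derive_seed(cfg.seed, "nmf")
    module_sets: dict[tuple[int, str], factorization.ModuleSet] = {}
    selected: dict[tuple[int, str], int] = {}
    for p in participants:
        for g in cfg.gravity_labels:
            scaled, sd = scale_unit_variance(normalized[(p, g)])
            n_sel, curve = factorization.select_module_number_incremental(
                scaled,
                N_max=cfg.n_max,
                threshold=cfg.vaf_threshold,
                n_folds=cfg.cv_folds,
                n_reps=cfg.cv_reps,
                n_restarts=cfg.cv_restarts,
                seed=nmf_seed + 97 * p + 13 * cfg.gravity_labels.index(g),
            )
            selected[(p, g)] = n_sel
            _write_json(out / "nmf" / f"vaf_curve_P{p:02d}_{g}.json", {
                "n_values": curve.n_values, "mean_vaf": curve.mean_vaf,
                "sd_vaf": curve.sd_vaf, "selected": n_sel,
            })

    # group-level module number per gravity (mode across participants)
    group_n = {
        g: factorization.group_module_number([selected[(p, g)] for p in participants])
        for g in cfg.gravity_labels
    }
    for p in participants:
        for g in cfg.gravity_labels:
            scaled, sd = scale_unit_variance(normalized[(p, g)])
            ms = factorization.nmf_extract(
                scaled, group_n[g],
                n_restarts=cfg.nmf_restarts,
                seed=nmf_seed + 1009 * p + 31 * cfg.gravity_labels.index(g),
                meta={"participant": p, "gravity": g, "unit_variance_sd": sd.tolist()},
            )
            module_sets[(p, g)] = ms

    # per-gravity clustering of spatial and temporal modules
    cl_seed = derive_seed(cfg.seed, "cluster")
    reps: dict[str, dict[str, np.ndarray]] = {"spatial": {}, "temporal": {}}
    for g in cfg.gravity_labels:
        for kind in ("spatial", "temporal"):
            vecs, labels = [], []
            for p in participants:
                ms = module_sets[(p, g)]
                mat = ms.W.T if kind == "spatial" else ms.C
                for mi, v in enumerate(mat):
                    vecs.append(v)
                    labels.append({"participant": p, "gravity": g, "module": mi, "kind": kind})
            pool = clustering.ModulePool.from_vectors(np.array(vecs), labels)
            res = clustering.spherical_kmeans(
                pool, group_n[g], n_init=cfg.cluster_inits, seed=cl_seed
            )
            res = clustering.dedupe_within_participant(res, pool)
            reps[kind][g] = clustering.representative_modules(res, pool)

    # cross-gravity constrained clustering of representatives
    cross = {}
    for kind in ("spatial", "temporal"):
        vecs, labels = [], []
        for g in cfg.gravity_labels:
            for mi, v in enumerate(reps[kind][g]):
                vecs.append(v)
                labels.append({"gravity": g, "module": mi, "kind": kind})
        pool = clustering.ModulePool.from_vectors(np.array(vecs), labels)
        pairs = clustering.same_gravity_pairs(labels)
        k_star, table, results = clustering.select_k_by_silhouette(
            pool, range(cfg.k_min, cfg.k_max + 1),
            constrained=True, cannot_link=pairs,
            n_init=cfg.cluster_inits, seed=cl_seed,
        )
        cross[kind] = {
            "k_star": k_star,
            "silhouette_table": {str(k): v for k, v in table.items()},
            "assignments": results[k_star].assignments if k_star in results else None,
            "item_labels": labels,
        }

    # similarity vs the reference (first) gravity level, with chance levels
    boot_seed = derive_seed(cfg.seed, "bootstrap")
    ref = cfg.gravity_labels[0]
    sim_report = {}
    for kind, metric in (("spatial", "cosine"), ("temporal", "correlation")):
        pool_all = np.vstack([reps[kind][g] for g in cfg.gravity_labels])
        chance = similarity.bootstrap_chance_level(
            pool_all, metric=metric, n_boot=cfg.n_boot, seed=boot_seed
        )
        per_gravity = {}
        for g in cfg.gravity_labels[1:]:
            m = similarity.match_modules(reps[kind][ref], reps[kind][g], metric=metric)
            per_gravity[g] = {
                "pairs": m.pairs,
                "similarities": m.similarities,
                "overall_median": m.overall_median,
                "above_chance": [s > chance.lower_bound for s in m.similarities],
            }
        sim_report[kind] = {"chance_level": chance.lower_bound, "vs_reference": per_gravity}

    report = {
        "settings": asdict(cfg),
        "selected_modules": {f"P{p:02d}/{g}": selected[(p, g)]
                             for p in participants for g in cfg.gravity_labels},
        "group_module_number": group_n,
        "cross_gravity_clustering": cross,
        "similarity": sim_report,
        "representatives": {
            kind: {g: reps[kind][g] for g in cfg.gravity_labels} for kind in reps
        },
        "elapsed_s": round(time.time() - t0, 2),
    }
    if gt is not None:
        report["ground_truth_modules"] = gt.n_modules
    _write_json(out / "condition_report.json", report)
    logger.info("condition analysis finished in %.1f s", time.time() - t0)
    return report


def run_tensor_analysis(cfg: AnalysisConfig, condition_report: dict | None = None) -> dict:
    """Tensor construction, nonnegative CP fit, gain summaries, and the
    NNLS cross-model fit of clustered representatives onto CP components."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    matrices, gt = _get_matrices(cfg)
    participants = sorted({p for p, _ in matrices})
    if not matrices:
        raise InvalidArgumentError("empty slice list")

    normalized = {}
    for p in participants:
        per_cond = {g: matrices[(p, g)] for g in cfg.gravity_labels}
        for g, m in normalize_amplitude(per_cond).items():
            normalized[(p, g)] = m

    slices, labels = [], []
    for p in participants:
        for g in cfg.gravity_labels:
            slices.append(normalized[(p, g)])
            labels.append({"participant": f"P{p:02d}", "gravity": g})
    emg_tensor = tensor.build_tensor(slices, labels)

    n_comp = cfg.tensor_components
    if n_comp is None and condition_report is not None:
        n_comp = max(
            condition_report["cross_gravity_clustering"]["spatial"]["k_star"],
            condition_report["cross_gravity_clustering"]["temporal"]["k_star"],
        )
    if n_comp is None:
        n_comp = cfg.n_modules_true
    model = tensor.ncp_decompose(
        emg_tensor, n_comp,
        n_restarts=cfg.tensor_restarts,
        seed=derive_seed(cfg.seed, "tensor"),
    )
    gains = tensor.summarize_gains(model, labels, by="gravity")

    report = {
        "tensor_shape": list(emg_tensor.shape),
        "n_components": n_comp,
        "vaf": model.vaf,
        "lambdas": model.lambdas,
        "per_gravity_gain_means": {g: gains[g] for g in cfg.gravity_labels},
        "elapsed_s": round(time.time() - t0, 2),
    }

    if condition_report is not None and "representatives" in condition_report:
        ref = cfg.gravity_labels[0]
        sp = np.asarray(condition_report["representatives"]["spatial"][ref])
        te = np.asarray(condition_report["representatives"]["temporal"][ref])
        report["cross_model_fit"] = {
            "spatial_vaf": similarity.nnls_reconstruct(sp, model.W_st).vaf,
            "temporal_vaf": similarity.nnls_reconstruct(te, model.C_st).vaf,
        }

    _write_json(out / "tensor_report.json", report)
    logger.info("tensor analysis finished in %.1f s", time.time() - t0)
    return report
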