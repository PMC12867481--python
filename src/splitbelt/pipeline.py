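"""End-to-end experiment runs: simulate → measure → fit → compare → report.

``run_experiment1`` reproduces the Ramp Down analysis on a synthetic cohort:
model fits and ΔBIC comparisons on the post-adaptation ramp, per-participant
recalibration levels, perceptual PSE bounds and compensation measures, their
correlation, and the range of ramp configurations without aftereffects.
``run_experiment2`` reproduces the Ramp Up & Down subgroup analysis:
flagged-stride counts on the first 60 strides, density-based clustering with
silhouette validation, and bootstrap comparisons of adaptation measures
between the discovered subgroups.

Reports are plain dictionaries (JSON-serializable) keyed by measure; a thin
click CLI wraps the two runners.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .clustering import auto_cluster, baseline_ci, count_flagged_strides
from .fitting import compare_models, fit_model, p_plateau_of, u_plateau_of
from .gait_metrics import fit_double_exponential, residual_variance, strides_to_plateau
from .models import MODEL_NAMES
from .paradigm import build_protocol, post_ramp_phase
from .perception import compensation_measures, pearson_correlation, pse_from_presses
from .stats import bootstrap_between_groups, bootstrap_group_ci, fdr_adjust
from .synthetic import generate_cohort


@dataclass
class RunConfig:
    """Configuration of one experiment run; all module defaults overridable."""

    experiment: str = "exp1"
    n_participants: int = 20
    memory_mix: float = 0.6
    adaptation_strides: int = 750
    baseline_strides: int = 120
    noise_sd: float = 0.02
    models: tuple[str, ...] = ("recal_map", "dual_state")
    n_boot: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError(f"experiment must be 'exp1' or 'exp2', got {self.experiment!r}")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models {sorted(unknown)}; available: {MODEL_NAMES}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _make_cohort(config: RunConfig, gt_sampler=None):
    schedule = build_protocol(
        config.experiment,
        adaptation_strides=config.adaptation_strides,
        baseline_strides=config.baseline_strides,
    )
    sampler = dict(gt_sampler or {})
    sampler.setdefault("noise_sd", lambda rng: config.noise_sd)
    return generate_cohort(
        n=config.n_participants,
        mix=config.memory_mix,
        schedule=schedule,
        gt_sampler=sampler,
        seed=config.seed,
    )


def _ci_dict(ci) -> dict:
    return {"mean": ci.mean, "ci": [ci.ci_lower, ci.ci_upper], "significant": ci.excludes_zero}


def run_experiment1(config: RunConfig, gt_sampler=None, cohort=None) -> dict:
    """Ramp Down analysis: model comparison, recalibration, and perception."""
    if config.experiment != "exp1":
        raise ValueError("run_experiment1 needs an exp1 config")
    cohort = cohort if cohort is not None else _make_cohort(config, gt_sampler)
    schedule = cohort[0].schedule
    ramp_phase = post_ramp_phase(schedule)
    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "experiment": "exp1",
        "n_participants": len(cohort),
    }

    fits = {name: [fit_model(name, part) for part in cohort] for name in config.models}
    if "recal_map" in fits:
        r_values = np.array([f.params["r"] for f in fits["recal_map"]])
        report["r_fit"] = {"per_participant": r_values.tolist(), "mean": float(r_values.mean())}
        comparisons = {}
        for name in config.models:
            if name == "recal_map":
                continue
            comp = compare_models(
                fits[name], fits["recal_map"],
                n_boot=config.n_boot, alpha=config.alpha, seed=config.seed,
            )
            comparisons[name] = _ci_dict(comp.ci)
        report["delta_bic_vs_recal_map"] = comparisons

    # perceptual measures: PSE bounds and percent compensation
    per_part = []
    if "recal_map" in fits:
        for idx, part in enumerate(cohort):
            if part.presses is None:
                continue
            bounds = pse_from_presses(part.schedule, *part.presses)
            per_part.append(
                compensation_measures(
                    bounds,
                    r_fit=fits["recal_map"][idx].params["r"],
                    p_plateau=p_plateau_of(part),
                    u_plateau=u_plateau_of(part),
                )
            )
    if per_part:
        report["pse_upper_mean"] = float(np.mean([m.pse_upper for m in per_part]))
        report["pse_lower_mean"] = float(np.mean([m.pse_lower for m in per_part]))
        report["comp_motor_recal_mean"] = float(np.mean([m.comp_motor_recal for m in per_part]))
        report["comp_motor_total_mean"] = float(np.mean([m.comp_motor_total for m in per_part]))
        report["comp_perceptual_upper_mean"] = float(
            np.mean([m.comp_perceptual_upper for m in per_part])
        )
        report["comp_perceptual_lower_mean"] = float(
            np.mean([m.comp_perceptual_lower for m in per_part])
        )
        recal = [m.comp_motor_recal for m in per_part]
        upper = [m.comp_perceptual_upper for m in per_part]
        if len(per_part) >= 3 and np.std(recal) > 0 and np.std(upper) > 0:
            r, p = pearson_correlation(recal, upper)
            report["corr_recal_vs_perceptual_upper"] = {"r": r, "p": p}

    # per-configuration aftereffect test on the ramp: sla CI vs zero, FDR family
    mask = schedule.phase_mask(ramp_phase)
    configs = schedule.table["config_index"].to_numpy()[mask]
    diffs = schedule.speed_diff[mask]
    sla = np.stack([part.gait.sla[mask] for part in cohort])
    family = []
    config_ids = np.unique(configs)
    for c in config_ids:
        per_participant = sla[:, configs == c].mean(axis=1)
        family.append(
            bootstrap_group_ci(per_participant, n_boot=config.n_boot,
                               alpha=config.alpha, seed=config.seed)
        )
    corrected = fdr_adjust(family, alpha=config.alpha)
    no_aftereffect = [
        {"config_index": int(c), "speed_diff": float(diffs[configs == c][0]), **_ci_dict(ci)}
        for c, ci in zip(config_ids, corrected)
        if not ci.excludes_zero
    ]
    report["no_aftereffect_configs"] = no_aftereffect
    _maybe_write(report, config)
    return report


def run_experiment2(config: RunConfig, gt_sampler=None, cohort=None) -> dict:
    """Ramp Up & Down subgroup analysis: flagged strides, clustering, statistics."""
    if config.experiment != "exp2":
        raise ValueError("run_experiment2 needs an exp2 config")
    cohort = cohort if cohort is not None else _make_cohort(config, gt_sampler)
    schedule = cohort[0].schedule
    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "experiment": "exp2",
        "n_participants": len(cohort),
    }

    base_mask = schedule.phase_mask("baseline_tied_2")
    ramp_mask = schedule.phase_mask(post_ramp_phase(schedule))
    adapt_mask = schedule.phase_mask("adaptation")
    counts, plateaus, var_decay = [], [], []
    for i, part in enumerate(cohort):
        ci = baseline_ci(part.gait.sla[base_mask], n_boot=config.n_boot, seed=config.seed + i)
        teal = part.gait.sla[ramp_mask][:60]  # speeds above the adaptation split
        counts.append(count_flagged_strides(teal, ci, direction="below"))
        adapt_sla = part.gait.sla[adapt_mask]
        plateaus.append(strides_to_plateau(adapt_sla)[0])
        fit = fit_double_exponential(adapt_sla)
        var_decay.append(
            residual_variance(fit.residuals, "first30") - residual_variance(fit.residuals, "last30")
        )
    counts = np.array(counts)
    result = auto_cluster(counts)
    report["flagged_stride_counts"] = counts.tolist()
    report["cluster_labels"] = result.labels.tolist()
    report["n_clusters"] = result.n_clusters
    report["cluster_sizes"] = result.cluster_sizes()
    report["silhouette_mean"] = result.silhouette_mean
    report["cluster_flag"] = result.flag

    if result.n_clusters == 2:
        # higher-count cluster = memory-based (cannot track larger perturbations)
        ids = sorted(result.cluster_sizes())
        means = {i: counts[result.labels == i].mean() for i in ids}
        memory_id = max(means, key=means.get)
        mem = result.labels == memory_id
        strct = (result.labels >= 0) & ~mem
        report["subgroup_sizes"] = {"memory": int(mem.sum()), "structure": int(strct.sum())}
        report["flagged_strides_between"] = _ci_dict(
            bootstrap_between_groups(counts[mem], counts[strct],
                                     n_boot=config.n_boot, alpha=config.alpha, seed=config.seed)
        )
        plateaus = np.array(plateaus, float)
        var_decay = np.array(var_decay, float)
        report["strides_to_plateau_between"] = _ci_dict(
            bootstrap_between_groups(plateaus[strct], plateaus[mem],
                                     n_boot=config.n_boot, alpha=config.alpha, seed=config.seed)
        )
        report["variance_decay_between"] = _ci_dict(
            bootstrap_between_groups(var_decay[strct], var_decay[mem],
                                     n_boot=config.n_boot, alpha=config.alpha, seed=config.seed)
        )
    _maybe_write(report, config)
    return report


def _maybe_write(report: dict, config: RunConfig) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / f"report_{config.experiment}.json").write_text(json.dumps(report, indent=2))


try:
    import click
except ImportError:  # pragma: no cover - click is a hard dependency in practice
    click = None

if click is not None:

    @click.group()
    def cli():
        """Split-belt adaptation analysis pipeline."""

    def _common(fn):
        fn = click.option("--seed", default=0, show_default=True)(fn)
        fn = click.option("--n", "n_participants", default=20, show_default=True)(fn)
        fn = click.option("--n-boot", default=10_000, show_default=True)(fn)
        fn = click.option("--noise-sd", default=0.02, show_default=True)(fn)
        fn = click.option("--adaptation-strides", default=750, show_default=True)(fn)
        fn = click.option("--out", "out_dir", default="splitbelt_run", show_default=True)(fn)
        return fn

    @cli.command()
    @_common
    @click.option("--models", default="recal_map,dual_state", show_default=True)
    def exp1(seed, n_participants, n_boot, noise_sd, adaptation_strides, out_dir, models):
        """Run the Ramp Down experiment on a synthetic cohort."""
        config = RunConfig(
            experiment="exp1", n_participants=n_participants, n_boot=n_boot,
            noise_sd=noise_sd, adaptation_strides=adaptation_strides,
            models=tuple(models.split(",")), seed=seed, out_dir=out_dir,
        )
        report = run_experiment1(config)
        click.echo(json.dumps({k: v for k, v in report.items() if k != "r_fit"}, indent=2))

    @cli.command()
    @_common
    def exp2(seed, n_participants, n_boot, noise_sd, adaptation_strides, out_dir):
        """Run the Ramp Up & Down subgroup experiment on a synthetic cohort."""
        config = RunConfig(
            experiment="exp2", n_participants=n_participants, n_boot=n_boot,
            noise_sd=noise_sd, adaptation_strides=adaptation_strides,
            seed=seed, out_dir=out_dir,
        )
        report = run_experiment2(config)
        click.echo(json.dumps(report, indent=2))

    @cli.command()
    @click.option("--experiment", type=click.Choice(["exp1", "exp2"]), default="exp1")
    @click.option("--n", "n_participants", default=20, show_default=True)
    @click.option("--seed", default=0, show_default=True)
    @click.option("--out", "out_dir", default="splitbelt_cohort", show_default=True)
    def simulate(experiment, n_participants, seed, out_dir):
        """Generate and export a synthetic cohort (CSV per participant + manifest)."""
        from .synthetic import export_cohort

        cohort = generate_cohort(n=n_participants, seed=seed, experiment=experiment)
        export_cohort(cohort, out_dir)
        click.echo(f"wrote {n_participants} participants to {out_dir}")
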