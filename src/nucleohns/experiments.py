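"""Ready-made experiments: compaction/binding reference point and
crowding sweeps.

These drivers wire the builder, the Langevin engine and the observables
pipeline together at desk scale.  Schedules are expressed in tau; the
integrator uses the published dt = 0.005 tau, so 1 tau = 200 steps.  The
compaction ratio always uses a *measured* baseline: a matched run with no
crowders and no H-NS defines Rg0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import aggregate, block_bootstrap_se
from .builder import SystemSpec
from .dynamics import IntegratorSettings, RunSchedule, run
from .presets import hns_concentration

__all__ = ["run_observables", "reference_point", "crowding_sweep"]


def _schedule(equil_tau: float, prod_tau: float, sample_tau: float, dt: float) -> RunSchedule:
    sample = max(1, round(sample_tau / dt))
    prod = round(prod_tau / dt)
    prod = (prod // sample) * sample
    return RunSchedule(
        equilibration_steps=round(equil_tau / dt),
        production_steps=prod,
        sample_interval=sample,
    )


def run_observables(
    spec: SystemSpec,
    equil_tau: float = 4_000.0,
    prod_tau: float = 12_000.0,
    sample_tau: float = 25.0,
    rg0: float | None = None,
    table=None,
):
    """Run one system and aggregate its observables.

    Returns (per-frame DataFrame, summary dict, run log)."""
    settings = IntegratorSettings(seed=spec.seed)
    schedule = _schedule(equil_tau, prod_tau, sample_tau, settings.dt)
    traj, log = run(spec, settings=settings, schedule=schedule, table=table)
    df, summary = aggregate(traj, rg0=rg0)
    return df, summary, log


def reference_point(
    seed: int = 1,
    n_monomers: int = 200,
    box_side: float = 50.0,
    n_hns: int = 30,
    phi_c: float = 0.0,
    n_replicas: int = 3,
    n_baseline_replicas: int = 2,
    equil_tau: float = 8_000.0,
    prod_tau: float = 12_000.0,
    sample_tau: float = 25.0,
    baseline_equil_tau: float | None = None,
    baseline_prod_tau: float | None = None,
) -> dict:
    """Compaction ratio and binding probability against a matched baseline.

    Runs ``n_replicas`` seeds of the (phi_c, n_hns) system and
    ``n_baseline_replicas`` of the (0, 0) baseline, pools production
    frames, and reports <Rg>/<Rg0> and theta with replica-aware errors.

    The binding degree of freedom is the slowest mode (theta needs
    ~1e4 tau to reach its plateau), hence the long default equilibration;
    the binder-free baseline relaxes within a few Rouse times, so it may
    use a shorter ``baseline_equil_tau`` (default: 4e3 tau).
    """
    if baseline_equil_tau is None:
        baseline_equil_tau = min(4_000.0, equil_tau)
    if baseline_prod_tau is None:
        # the baseline needs no binding equilibration, so its budget goes
        # into production sampling of Rg0 (the ratio's denominator)
        baseline_prod_tau = prod_tau + (equil_tau - baseline_equil_tau)
    ss = np.random.SeedSequence(seed)
    child = [int(s) & 0x7FFFFFFF for s in ss.generate_state(n_replicas + n_baseline_replicas)]

    rg_means, theta_series, rg_series = [], [], []
    fd_list, fb_list = [], []
    for r in range(n_replicas):
        spec = SystemSpec(
            n_monomers=n_monomers, box_side=box_side, phi_c=phi_c,
            n_hns=n_hns, seed=child[r],
        )
        df, summary, _ = run_observables(spec, equil_tau, prod_tau, sample_tau)
        rg_series.append(df["rg"].to_numpy())
        theta_series.append(df["theta"].to_numpy())
        rg_means.append(summary["rg_mean"])
        fd_list.append(summary["frac_dangling_mean"])
        fb_list.append(summary["frac_bridging_mean"])

    rg0_series = []
    for r in range(n_baseline_replicas):
        spec0 = SystemSpec(
            n_monomers=n_monomers, box_side=box_side, phi_c=0.0, n_hns=0,
            seed=child[n_replicas + r],
        )
        df0, summary0, _ = run_observables(
            spec0, baseline_equil_tau, baseline_prod_tau, sample_tau
        )
        rg0_series.append(df0["rg"].to_numpy())

    rg_all = np.concatenate(rg_series)
    rg0_all = np.concatenate(rg0_series)
    theta_all = np.concatenate(theta_series)
    # blocks of ~1 replica-third: longer than the slow (~few 1e3 tau)
    # correlation time of Rg and theta, so the bootstrap is not overconfident
    rg_mean, rg0_mean = rg_all.mean(), rg0_all.mean()
    rg_se = block_bootstrap_se(rg_all, n_blocks=3 * n_replicas)
    rg0_se = block_bootstrap_se(rg0_all, n_blocks=3 * n_baseline_replicas)
    ratio = rg_mean / rg0_mean
    ratio_se = ratio * np.hypot(rg_se / rg_mean, rg0_se / rg0_mean)
    return {
        "n_frames": int(len(rg_all)),
        "rg_mean": float(rg_mean),
        "rg0_mean": float(rg0_mean),
        "compaction_ratio": float(ratio),
        "compaction_ratio_se": float(ratio_se),
        "theta": float(theta_all.mean()),
        "theta_se": float(block_bootstrap_se(theta_all, n_blocks=3 * n_replicas)),
        "frac_dangling": float(np.mean(fd_list)),
        "frac_bridging": float(np.mean(fb_list)),
        "hns_concentration_uM": hns_concentration(n_hns, box_side),
    }


def crowding_sweep(
    seed: int = 1,
    phi_values=(0.0, 0.1, 0.2),
    n_monomers: int = 50,
    box_side: float = 20.0,
    n_hns: int = 8,
    n_replicas: int = 1,
    equil_tau: float = 1_500.0,
    prod_tau: float = 5_000.0,
    sample_tau: float = 12.5,
) -> pd.DataFrame:
    """Small-system sweep over crowder volume fraction.

    Returns a tidy table keyed by (phi_c, n_hns, seed) with compaction,
    binding-mode fractions and mean cluster size — the qualitative
    synergy readout (compaction deepens, bridging and clustering grow
    with phi_c).
    """
    ss = np.random.SeedSequence(seed)
    n_cond = len(phi_values)
    child = np.array(
        [int(s) & 0x7FFFFFFF for s in ss.generate_state((n_cond + 1) * n_replicas)]
    ).reshape(n_cond + 1, n_replicas)

    # baseline Rg0 (phi=0, no H-NS)
    rg0_vals = []
    for r in range(n_replicas):
        spec0 = SystemSpec(
            n_monomers=n_monomers, box_side=box_side, phi_c=0.0, n_hns=0,
            seed=int(child[0, r]),
        )
        _, s0, _ = run_observables(spec0, equil_tau, prod_tau, sample_tau)
        rg0_vals.append(s0["rg_mean"])
    rg0 = float(np.mean(rg0_vals))

    rows = []
    for ci, phi in enumerate(phi_values):
        for r in range(n_replicas):
            spec = SystemSpec(
                n_monomers=n_monomers, box_side=box_side, phi_c=phi,
                n_hns=n_hns, seed=int(child[ci + 1, r]),
            )
            df, summary, log = run_observables(
                spec, equil_tau, prod_tau, sample_tau, rg0=rg0
            )
            rows.append(
                dict(
                    phi_c=phi,
                    n_hns=n_hns,
                    hns_uM=hns_concentration(n_hns, box_side),
                    seed=spec.seed,
                    rg=summary["rg_mean"],
                    rg_se=summary["rg_se"],
                    rg0=rg0,
                    compaction_ratio=summary["rg_mean"] / rg0,
                    theta=summary["theta_mean"],
                    frac_dangling=summary["frac_dangling_mean"],
                    frac_bridging=summary["frac_bridging_mean"],
                    mean_cluster_size=summary["mean_cluster_size"],
                    mean_temperature=log["mean_temperature"],
                )
            )
    return pd.DataFrame(rows)
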