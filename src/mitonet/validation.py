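"""Randomness calibration checks for the pcf / nndist machinery.

These routines re-create the tool's validation experiments: uniformly random
points placed on synthetic test networks must give an IRP-normalized pcf of
1 at all distances, independent of point density and of network
connectivity, and an nndist ratio of 1. Each "image" follows the estimation
protocol used for the validation experiments: the observed side is averaged
over several random distributions (single random patterns fluctuate wildly
at low density), and the baseline is the average over IRP replicates; the
per-condition curves are then averaged across images before the ratio of
observed to baseline is summarized over the distance window.
"""

from __future__ import annotations

import numpy as np

from .linear_pcf import PcfConfig, nndist, pooled_pcf, simulate_irp
from .network_distances import GeodesicStructure
from .network_graph import LinearNetwork

__all__ = ["irp_pcf_calibration", "irp_nndist_calibration"]

#: standard low / high nucleoid densities (points per um of network) used by
#: the synthetic validation suites
DENSITY_LOW = 0.05
DENSITY_HIGH = 0.25


def irp_pcf_calibration(
    network: LinearNetwork,
    densities: tuple[float, ...] = (DENSITY_LOW, DENSITY_HIGH),
    n_patterns: int = 20,
    n_average: int = 6,
    r_window_um: tuple[float, float] | None = None,
    config: PcfConfig | None = None,
    seed: int = 0,
) -> dict:
    """Mean IRP-normalized pooled pcf for uniform random points.

    For each density, ``n_patterns`` images are simulated; each contributes
    ``n_average`` observed random distributions and ``n_average`` IRP
    baseline replicates with the same point count. Per density the averaged
    observed curve is divided by the averaged baseline curve and the ratio
    is averaged over ``r_window_um`` (default: one kernel bandwidth to 3 um).
    Returns per-density values and their mean; 1 is the random expectation.
    """
    config = config or PcfConfig()
    geo = GeodesicStructure(network)
    ps = network.pixel_size
    r = config.r_grid_um(ps)
    if r_window_um is None:
        r_window_um = (config.bandwidth_um(ps), 3.0)
    win = (r >= r_window_um[0]) & (r <= r_window_um[1])
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    total = network.total_length_um
    per_density = {}
    n_points_total = 0
    for dens in densities:
        n = int(round(dens * total))
        obs, base = [], []
        for _ in range(n_patterns):
            for _ in range(n_average):
                obs.append(pooled_pcf(simulate_irp(network, n, rng), network, config=config, geo=geo).g)
                base.append(pooled_pcf(simulate_irp(network, n, rng), network, config=config, geo=geo).g)
            n_points_total += n
        denom = np.mean(base, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(denom > 0, np.mean(obs, axis=0) / denom, np.nan)
        per_density[dens] = float(np.nanmean(ratio[win]))
    return {
        "per_density": per_density,
        "mean": float(np.mean(list(per_density.values()))),
        "n_points_total": n_points_total,
    }


def irp_nndist_calibration(
    network: LinearNetwork,
    n: int = 50,
    n_trials: int = 50,
    n_replicates: int = 6,
    seed: int = 0,
) -> dict:
    """Mean nndist ratio (observed / IRP baseline) when the observed pattern
    is itself an independent random process; 1 is the random expectation."""
    geo = GeodesicStructure(network)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ratios = []
    for _ in range(n_trials):
        actual = nndist(simulate_irp(network, n, rng), geo=geo).mean
        base = np.mean(
            [nndist(simulate_irp(network, n, rng), geo=geo).mean for _ in range(n_replicates)]
        )
        ratios.append(actual / base)
    return {"mean": float(np.mean(ratios)), "sd": float(np.std(ratios)), "n": n}
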