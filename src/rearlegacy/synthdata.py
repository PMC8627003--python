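"""Synthetic data with known ground truth for every pipeline stage.

The community generator emulates the statistical structure of a two-source
rearing experiment: larvae acquire their gut community from one of two
rearing environments (a species-poor, highly variable flow-through source
versus a species-rich, homogeneous biofloc source), then converge toward a
shared recirculating-system community over successive timepoints while a
small planted core persists everywhere.  Counts are Dirichlet-multinomial
(overdispersed) at realistic sequencing depths, and configurable correlated
ASV blocks are planted per treatment for network recovery tests.

The growth-trial and digestibility generators invert the corresponding
estimator formulas from known true parameters, so the estimators' parameter
recovery can be verified exactly (no noise) or in expectation (with noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .asv import AsvTable
from .bioenergetics import CompositionProfile, TankGrowthRecord

__all__ = [
    "CommunityScenario",
    "SyntheticTruth",
    "simulate_asv_experiment",
    "simulate_growth_trial",
    "simulate_digestibility",
]


@dataclass
class CommunityScenario:
    """Parameters of the two-source convergence experiment.

    The defaults describe the study conditions the generator emulates: a
    species-poor flow-through (FTS) source with high tank-to-tank
    variability, a species-rich biofloc (BFS) source with low variability,
    three sampling timepoints with non-decreasing convergence ``kappa``
    toward a common recirculating-system (RAS) community, eight persistent
    core ASVs, sequencing depths drawn uniformly from the observed range,
    and per-system planted correlation blocks (the biofloc history carries
    more positive microbial associations).
    """

    n_asvs: int = 150
    n_core: int = 8
    timepoints: tuple = (15, 63, 105)
    #: convergence toward the shared RAS community, per timepoint, in [0, 1]
    kappa: Mapping[int, float] = field(
        default_factory=lambda: {15: 0.0, 63: 0.75, 105: 0.9}
    )
    tanks_per_treatment: int = 3
    #: fish sampled per tank at each timepoint
    fish_per_tank: Mapping[int, int] = field(
        default_factory=lambda: {15: 5, 63: 5, 105: 3}
    )
    depth_range: tuple = (3380, 30442)
    # source community structure
    fts_richness: int = 40
    bfs_richness: int = 120
    ras_richness: int = 100
    fts_core_fraction: float = 0.5
    bfs_core_fraction: float = 0.03
    ras_core_fraction: float = 0.3
    #: Dirichlet concentration (low = high inter-replicate dissimilarity)
    fts_theta: float = 15.0
    bfs_theta: float = 300.0
    ras_theta: float = 150.0
    #: minimum proportion of each core ASV in every community
    core_floor: float = 0.002
    #: planted correlated blocks per system: list of (size, sign)
    blocks: Mapping[str, Sequence[tuple]] = field(
        default_factory=lambda: {
            "FTS": [(6, 1)],
            "BFS": [(6, 1), (6, 1), (5, -1)],
        }
    )
    block_sigma: float = 0.8
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        # configs may arrive via JSON/YAML where mapping keys become strings
        self.timepoints = tuple(int(t) for t in self.timepoints)
        self.kappa = {int(k): float(v) for k, v in self.kappa.items()}
        self.fish_per_tank = {int(k): int(v) for k, v in self.fish_per_tank.items()}
        self.depth_range = tuple(int(d) for d in self.depth_range)

    def validate(self) -> None:
        if self.n_core < 0 or self.n_core > self.n_asvs:
            raise ValueError("n_core must lie in [0, n_asvs]")
        ks = [self.kappa[t] for t in self.timepoints]
        if any(not 0 <= k <= 1 for k in ks):
            raise ValueError("kappa values must lie in [0, 1]")
        if any(b > a + 1e-12 for a, b in zip(ks[1:], ks[:-1])):
            raise ValueError("kappa must be non-decreasing over timepoints")
        if self.n_core * self.core_floor >= 1.0:
            raise ValueError("core floors exceed the simplex")
        if self.depth_range[0] <= 0 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("invalid depth range")
        for r, c in (
            (self.fts_richness, self.fts_core_fraction),
            (self.bfs_richness, self.bfs_core_fraction),
            (self.ras_richness, self.ras_core_fraction),
        ):
            if r <= self.n_core or not 0 <= c < 1:
                raise ValueError("source richness/core fraction invalid")


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside generated data.

    Only the fields relevant to the generating function are populated.
    """

    compositions: Optional[pd.DataFrame] = None  # realised per-sample proportions
    core_asvs: Optional[frozenset] = None
    blocks: Optional[dict] = None  # system -> list of (asv tuple, sign)
    true_adc: Optional[dict] = None
    true_sgr: Optional[float] = None
    true_w_final: Optional[float] = None
    params: dict = field(default_factory=dict)


def _source_composition(
    rng, n_asvs, core_idx, support_idx, core_fraction, core_floor
) -> np.ndarray:
    """Random base composition on a fixed support with a core mass fraction."""
    comp = np.zeros(n_asvs)
    n_core = len(core_idx)
    non_core = [i for i in support_idx if i not in set(core_idx)]
    comp[core_idx] = rng.dirichlet(np.ones(n_core) * 2.0) * core_fraction
    comp[non_core] = rng.dirichlet(np.ones(len(non_core)) * 0.7) * (1 - core_fraction)
    # enforce the per-ASV core floor, renormalising the rest
    deficit = np.maximum(core_floor - comp[core_idx], 0.0)
    if deficit.sum() > 0:
        comp[core_idx] += deficit
        comp /= comp.sum()
    return comp


def simulate_asv_experiment(
    scenario: Optional[CommunityScenario] = None,
) -> tuple[AsvTable, SyntheticTruth]:
    """Generate the full two-source, three-timepoint ASV experiment.

    Per sample the expected composition is ``(1 - kappa) * source +
    kappa * RAS`` at its timepoint's convergence level; the realised
    composition is a Dirichlet draw around it (concentration interpolated
    between the source's and the RAS's), modulated by the sample's planted
    block factors, and counts are a multinomial draw at a depth sampled
    uniformly from the configured range.
    """
    scenario = scenario or CommunityScenario()
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_asvs
    asv_ids = [f"ASV{i + 1}" for i in range(n)]
    core_idx = list(range(scenario.n_core))
    core_set = frozenset(asv_ids[i] for i in core_idx)

    non_core_pool = np.arange(scenario.n_core, n)
    supports = {}
    for name, richness in (
        ("FTS", scenario.fts_richness),
        ("BFS", scenario.bfs_richness),
        ("RAS", scenario.ras_richness),
    ):
        extra = rng.choice(non_core_pool, size=richness - scenario.n_core, replace=False)
        supports[name] = core_idx + sorted(int(i) for i in extra)

    comps = {
        "FTS": _source_composition(
            rng, n, core_idx, supports["FTS"], scenario.fts_core_fraction,
            scenario.core_floor,
        ),
        "BFS": _source_composition(
            rng, n, core_idx, supports["BFS"], scenario.bfs_core_fraction,
            scenario.core_floor,
        ),
        "RAS": _source_composition(
            rng, n, core_idx, supports["RAS"], scenario.ras_core_fraction,
            scenario.core_floor,
        ),
    }
    thetas = {"FTS": scenario.fts_theta, "BFS": scenario.bfs_theta}

    # assign planted blocks within the RAS support so they persist over time
    ras_support = [i for i in supports["RAS"] if i not in set(core_idx)]
    available = list(ras_support)
    block_truth: dict = {}
    for system, specs in scenario.blocks.items():
        block_truth[system] = []
        for size, sign in specs:
            if size > len(available):
                raise ValueError("not enough ASVs left for planted blocks")
            pick = [available.pop(rng.integers(len(available))) for _ in range(size)]
            block_truth[system].append((tuple(asv_ids[i] for i in pick), int(sign)))

    final_t = scenario.timepoints[-1]
    records = []
    rows = []
    comp_rows = []
    for t in scenario.timepoints:
        kappa = scenario.kappa[t]
        fish = scenario.fish_per_tank[t]
        for system in ("FTS", "BFS"):
            diets = ("M-NSP", "H-NSP") if t == final_t else ("starter",)
            base = (1 - kappa) * comps[system] + kappa * comps["RAS"]
            theta = (1 - kappa) * thetas[system] + kappa * scenario.ras_theta
            for diet in diets:
                for tank_i in range(scenario.tanks_per_treatment):
                    tank = chr(ord("A") + tank_i)
                    for f in range(fish):
                        p = _draw_sample_proportions(
                            rng, base, theta, core_idx, scenario.core_floor
                        )
                        p = _apply_blocks(
                            rng, p, asv_ids, block_truth.get(system, []),
                            scenario.block_sigma,
                        )
                        depth = int(
                            rng.integers(scenario.depth_range[0],
                                         scenario.depth_range[1] + 1)
                        )
                        counts = rng.multinomial(depth, p)
                        sid = f"t{t}_{system}_{diet}_{tank}_{f + 1}"
                        records.append(counts)
                        comp_rows.append(p)
                        rows.append(
                            {
                                "sample": sid,
                                "system": system,
                                "diet": diet,
                                "timepoint": t,
                                "tank": f"{system}-{diet}-{tank}",
                                "fish": f + 1,
                            }
                        )
    meta = pd.DataFrame(rows).set_index("sample")
    counts = pd.DataFrame(np.vstack(records), index=meta.index, columns=asv_ids)
    table = AsvTable(counts, meta)
    truth = SyntheticTruth(
        compositions=pd.DataFrame(
            np.vstack(comp_rows), index=meta.index, columns=asv_ids
        ),
        core_asvs=core_set,
        blocks=block_truth,
        params={"scenario": scenario},
    )
    return table, truth


def _draw_sample_proportions(rng, base, theta, core_idx, core_floor):
    support = base > 0
    alpha = base[support] * theta
    p = np.zeros_like(base)
    p[support] = rng.dirichlet(alpha)
    # keep the persistent core above its floor in the realised sample too
    deficit = np.maximum(core_floor * 0.5 - p[core_idx], 0.0)
    if deficit.sum() > 0:
        p[core_idx] += deficit
        p /= p.sum()
    return p


def _apply_blocks(rng, p, asv_ids, blocks, sigma):
    if not blocks:
        return p
    index = {a: i for i, a in enumerate(asv_ids)}
    p = p.copy()
    for asvs, sign in blocks:
        f = float(np.exp(rng.normal(0.0, sigma)))
        idx = [index[a] for a in asvs]
        if sign > 0:
            p[idx] = p[idx] * f
        else:
            half = len(idx) // 2
            p[idx[:half]] = p[idx[:half]] * f
            p[idx[half:]] = p[idx[half:]] / f
    return p / p.sum()


# -- growth trial ---------------------------------------------------------

def simulate_growth_trial(
    true_sgr: float,
    w_initial: float = 7.2,
    duration: float = 41.0,
    n_tanks: int = 3,
    noise: float = 0.0,
    seed: Optional[int] = None,
    n_fish: int = 30,
    ration: float = 20.0,
    ration_exponent: float = 0.8,
) -> tuple[list[TankGrowthRecord], SyntheticTruth]:
    """Generate tank growth records from a known true specific growth rate.

    Final weight follows the exponential growth model
    ``w_f = w_i * exp(sgr * t / 100)`` with optional multiplicative
    log-normal tank noise of scale ``noise`` (mean-one).  Daily feed intake
    follows a metabolic-weight ration of ``ration`` g per kg^exponent body
    weight per day, averaged along the true growth trajectory.
    """
    if true_sgr <= 0 or w_initial <= 0 or duration <= 0 or n_tanks <= 0:
        raise ValueError("parameters must be positive")
    rng = np.random.default_rng(seed)
    w_final_true = w_initial * np.exp(true_sgr * duration / 100.0)
    days = np.arange(duration)
    w_t = w_initial * np.exp(true_sgr * days / 100.0)
    feed_daily = ration * (w_t / 1000.0) ** ration_exponent
    fi = float(feed_daily.mean())
    records = []
    for _ in range(n_tanks):
        if noise > 0:
            eps = rng.normal(-0.5 * noise ** 2, noise)
            w_f = float(w_final_true * np.exp(eps))
        else:
            w_f = float(w_final_true)
        records.append(
            TankGrowthRecord(
                n_initial=n_fish,
                n_final=n_fish,
                w_initial=w_initial,
                w_final=w_f,
                duration=duration,
                feed_intake=fi,
            )
        )
    truth = SyntheticTruth(
        true_sgr=true_sgr,
        true_w_final=float(w_final_true),
        params={
            "w_initial": w_initial,
            "duration": duration,
            "noise": noise,
            "feed_intake": fi,
        },
    )
    return records, truth


# -- digestibility --------------------------------------------------------

def simulate_digestibility(
    true_adc: Mapping[str, float],
    feed: CompositionProfile,
    n_samples: int = 3,
    noise: float = 0.0,
    seed: Optional[int] = None,
    marker_concentration_factor: float = 3.0,
) -> tuple[list[CompositionProfile], SyntheticTruth]:
    """Generate faeces profiles whose marker ratios encode known true ADCs.

    The inert marker concentrates in faeces by ``marker_concentration_factor``
    (nutrients are absorbed, the marker is not); each nutrient's
    faeces-to-marker ratio equals the feed ratio times ``(1 - true ADC)``,
    with optional mean-one multiplicative log-normal noise.  Applying the ADC
    estimator to the output recovers the truth exactly at zero noise and in
    expectation otherwise.
    """
    rng = np.random.default_rng(seed)
    for nut, a in true_adc.items():
        if not 0.0 <= a <= 1.0:
            raise ValueError(f"true ADC for {nut!r} must lie in [0, 1]")
    y_feed = feed.nutrient("yttrium")
    if y_feed <= 0:
        raise ValueError("feed must contain the yttrium marker")
    y_faeces = y_feed * marker_concentration_factor
    out = []
    for _ in range(n_samples):
        kwargs = {"role": "faeces", "yttrium": y_faeces}
        for nut, a in true_adc.items():
            base = (1.0 - a) * feed.nutrient(nut) * marker_concentration_factor
            if noise > 0:
                base *= float(np.exp(rng.normal(-0.5 * noise ** 2, noise)))
            kwargs[nut] = base
        out.append(CompositionProfile(**kwargs))
    truth = SyntheticTruth(
        true_adc=dict(true_adc),
        params={"noise": noise, "marker_concentration_factor": marker_concentration_factor},
    )
    return out, truth
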