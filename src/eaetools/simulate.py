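"""Synthetic data generators with known ground truth.

Every downstream stage of the pipeline (two-channel array preprocessing,
regularized-t differential expression, concordance, qPCR quantification,
clinical-score analytics) is exercised against data produced here, so each
generator returns both the observable table and a truth ledger recording the
uncorrupted values and every injected artifact.

The array generator emulates a pooled-RNA two-color hybridization: one array
per condition, reference channel = vehicle pool, sample channel = treatment
pool, three replicate probes per gene, plus negative-control and spike-in
control spots.  Corruptions are applied in the order a real scan acquires
them: per-spot log-normal noise, a smooth intensity-dependent dye bias on the
sample channel, an additive background offset on both channels (which
attenuates log-ratios near the detection limit), and rare gross one-channel
outliers mimicking dust or array imperfections.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "GroupScoreProfile",
    "ScoreSimParams",
    "build_ground_truth",
    "simulate_two_channel_scan",
    "simulate_qpcr_experiment",
    "simulate_score_trajectories",
    "simulate_correlated_log2fc",
]

EXPERIMENTAL = "experimental"
NEGATIVE_CONTROL = "negative_control"
SPIKE_IN = "spike_in"


@dataclass(frozen=True)
class SimulationParams:
    """Generative knobs for a two-channel array scan.

    Defaults encode the treatment-signature structure of the study design
    this pipeline targets: a down-regulated inflammatory set with log2
    effects in [-3, -1] (i.e. more than 2-fold down), an up-regulated set
    with effects in [+0.6, +2], and a large null majority; three replicate
    probes per gene; and enough replicated control spots to calibrate the
    technical-noise model.

    Parameters
    ----------
    n_genes : number of experimental genes on the array.
    frac_down, frac_up : fractions of genes carrying down/up effects
        (``floor`` rounding; the remainder is exactly null).
    down_effect_range, up_effect_range : log2 effect ranges (uniform draw).
    baseline_log2_intensity_range : per-gene baseline abundance range, log2
        linear-intensity units.
    noise_sd : SD of the per-spot log2-ratio noise (log2 units); this is the
        generative value of the intra-array technical variability
        ``sigma_tech`` that the preprocessing module estimates from controls.
    dye_bias_amplitude : maximum log2 shift of the sample channel at the low
        end of the intensity range (0 disables the bias); must stay below
        half the baseline range so the distortion remains monotone.
    background_offset : additive offset, linear intensity units, applied to
        both channels (models unsubtracted background; attenuates ratios of
        genes near the detection limit).
    outlier_rate : per-experimental-spot probability of a gross artifact.
    outlier_magnitude : size of the artifact, log2 units, random sign,
        applied to the sample channel only.
    n_replicate_probes : replicate spots per gene (>= 2, default 3).
    n_control_spots : total spike-in control spots, split evenly over
        ``n_spikein_probes`` replicated families spanning the intensity
        range; these calibrate sigma_tech.
    n_negative_controls : spots with no complementary target, both channels
        at background level; these calibrate the detection limit.
    """

    n_genes: int = 2000
    frac_down: float = 0.05
    frac_up: float = 0.05
    down_effect_range: tuple[float, float] = (-3.0, -1.0)
    up_effect_range: tuple[float, float] = (0.6, 2.0)
    baseline_log2_intensity_range: tuple[float, float] = (6.0, 16.0)
    noise_sd: float = 0.15
    dye_bias_amplitude: float = 0.0
    background_offset: float = 0.0
    outlier_rate: float = 0.0
    outlier_magnitude: float = 3.0
    n_replicate_probes: int = 3
    n_control_spots: int = 1000
    n_negative_controls: int = 500
    n_spikein_probes: int = 20
    neg_control_log2_level: float = 6.0
    neg_control_log2_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("frac_down", "frac_up", "outlier_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_down + self.frac_up > 1.0:
            raise ValueError("frac_down + frac_up must be <= 1")
        if self.n_replicate_probes < 2:
            raise ValueError("n_replicate_probes must be >= 2")
        for name in ("down_effect_range", "up_effect_range",
                     "baseline_log2_intensity_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi)")
        if self.noise_sd < 0 or self.neg_control_log2_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        lo, hi = self.baseline_log2_intensity_range
        if self.dye_bias_amplitude < 0:
            raise ValueError("dye_bias_amplitude must be >= 0")
        if self.dye_bias_amplitude >= (hi - lo) / 2.0:
            raise ValueError(
                "dye_bias_amplitude must be < half the baseline log2 range "
                "to keep the distortion monotone"
            )
        if self.background_offset < 0:
            raise ValueError("background_offset must be >= 0")


@dataclass
class GroundTruth:
    """Truth ledger: per-gene effects plus, once a scan has been simulated,
    the per-spot pre-corruption values and injected-outlier flags."""

    genes: pd.DataFrame          # gene_id, true_log2_effect, regulated
    spots: pd.DataFrame | None = None  # filled by simulate_two_channel_scan

    @property
    def n_outliers_injected(self) -> int:
        if self.spots is None:
            return 0
        return int(self.spots["outlier_injected"].sum())


def build_ground_truth(params: SimulationParams) -> GroundTruth:
    """Draw per-gene true log2 effects.

    ``floor(frac_down * n_genes)`` genes get a uniform draw from the down
    range, ``floor(frac_up * n_genes)`` from the up range, the remainder are
    exactly 0.  Which genes carry effects is randomized; deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_genes
    n_down = int(np.floor(params.frac_down * n))
    n_up = int(np.floor(params.frac_up * n))
    order = rng.permutation(n)
    effects = np.zeros(n)
    labels = np.full(n, "null", dtype=object)
    down_idx = order[:n_down]
    up_idx = order[n_down:n_down + n_up]
    effects[down_idx] = rng.uniform(*params.down_effect_range, size=n_down)
    effects[up_idx] = rng.uniform(*params.up_effect_range, size=n_up)
    labels[down_idx] = "down"
    labels[up_idx] = "up"
    width = len(str(n - 1))
    genes = pd.DataFrame({
        "gene_id": [f"gene_{i:0{width}d}" for i in range(n)],
        "true_log2_effect": effects,
        "regulated": labels,
    })
    return GroundTruth(genes=genes)


def _dye_bias(log2_x: np.ndarray, amplitude: float,
              lo: float, hi: float) -> np.ndarray:
    # Smooth monotone distortion, largest at low intensity: the classic
    # banana-shaped MA bias that quantile normalization must remove.
    u = np.clip((hi - log2_x) / (hi - lo), 0.0, 1.0)
    return log2_x + amplitude * u ** 2


def simulate_two_channel_scan(
    truth: GroundTruth,
    params: SimulationParams,
    *,
    array_id: str = "array_1",
    condition: str = "treatment",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one two-channel scan for the given gene truth.

    Returns the scan table (one row per spot) and a new :class:`GroundTruth`
    whose ``spots`` ledger records each experimental spot's pre-corruption
    log2 ratio and whether a gross outlier was injected.
    """
    if len(truth.genes) != params.n_genes:
        raise ValueError("truth and params disagree on n_genes")
    rng = np.random.default_rng([params.seed, 1])
    lo, hi = params.baseline_log2_intensity_range
    R = params.n_replicate_probes
    n = params.n_genes

    baseline = rng.uniform(lo, hi, size=n)
    gene_ids = truth.genes["gene_id"].to_numpy()
    effects = truth.genes["true_log2_effect"].to_numpy()

    # experimental spots: gene-major order, replicate_index 1..R
    g_idx = np.repeat(np.arange(n), R)
    rep_idx = np.tile(np.arange(1, R + 1), n)
    ref_log2 = baseline[g_idx] + rng.normal(0.0, params.noise_sd, size=n * R)
    ratio_clean = effects[g_idx] + rng.normal(0.0, params.noise_sd, size=n * R)
    smp_log2 = ref_log2 + ratio_clean

    # spike-in control families spanning the intensity range, null effect
    fam_n = params.n_control_spots // params.n_spikein_probes
    spike_base = np.linspace(lo, hi, params.n_spikein_probes)
    sp_fam = np.repeat(np.arange(params.n_spikein_probes), fam_n)
    sp_rep = np.tile(np.arange(1, fam_n + 1), params.n_spikein_probes)
    sp_ref = spike_base[sp_fam] + rng.normal(0.0, params.noise_sd,
                                             size=sp_fam.size)
    sp_smp = sp_ref + rng.normal(0.0, params.noise_sd, size=sp_fam.size)

    # negative controls: background level, channels independent
    m = params.n_negative_controls
    neg_ref = rng.normal(params.neg_control_log2_level,
                         params.neg_control_log2_sd, size=m)
    neg_smp = rng.normal(params.neg_control_log2_level,
                         params.neg_control_log2_sd, size=m)

    if params.dye_bias_amplitude > 0:
        smp_log2 = _dye_bias(smp_log2, params.dye_bias_amplitude, lo, hi)
        sp_smp = _dye_bias(sp_smp, params.dye_bias_amplitude, lo, hi)
        neg_smp = _dye_bias(neg_smp, params.dye_bias_amplitude, lo, hi)

    out_flag = rng.random(n * R) < params.outlier_rate
    out_sign = np.where(rng.random(n * R) < 0.5, -1.0, 1.0)
    smp_log2 = smp_log2 + out_flag * out_sign * params.outlier_magnitude

    b = params.background_offset
    frames = []
    frames.append(pd.DataFrame({
        "probe_id": [f"{gene_ids[g]}_r{r}" for g, r in zip(g_idx, rep_idx)],
        "gene_id": gene_ids[g_idx],
        "replicate_index": rep_idx,
        "probe_class": EXPERIMENTAL,
        "intensity_sample": 2.0 ** smp_log2 + b,
        "intensity_reference": 2.0 ** ref_log2 + b,
    }))
    frames.append(pd.DataFrame({
        "probe_id": [f"spike_{f:02d}" for f in sp_fam],
        "gene_id": [f"spike_{f:02d}" for f in sp_fam],
        "replicate_index": sp_rep,
        "probe_class": SPIKE_IN,
        "intensity_sample": 2.0 ** sp_smp + b,
        "intensity_reference": 2.0 ** sp_ref + b,
    }))
    frames.append(pd.DataFrame({
        "probe_id": "neg_ctrl",
        "gene_id": "neg_ctrl",
        "replicate_index": np.arange(1, m + 1),
        "probe_class": NEGATIVE_CONTROL,
        "intensity_sample": 2.0 ** neg_smp + b,
        "intensity_reference": 2.0 ** neg_ref + b,
    }))
    scan = pd.concat(frames, ignore_index=True)
    scan.insert(0, "condition", condition)
    scan.insert(0, "array_id", array_id)

    spots = pd.DataFrame({
        "array_id": array_id,
        "gene_id": gene_ids[g_idx],
        "replicate_index": rep_idx,
        "true_log2_effect": effects[g_idx],
        "clean_log2_ratio": ratio_clean,
        "baseline_log2_intensity": baseline[g_idx],
        "outlier_injected": out_flag,
        "outlier_delta": out_flag * out_sign * params.outlier_magnitude,
    })
    return scan, GroundTruth(genes=truth.genes.copy(), spots=spots)


# ---------------------------------------------------------------------------
# qPCR

def simulate_qpcr_experiment(
    genes: Sequence[str],
    group_sizes: Mapping[str, int],
    effects: Mapping[tuple[str, str], float],
    *,
    endogenous_gene: str = "Gapdh",
    vehicle_group: str = "Vehicle",
    base_cp: Mapping[str, float] | None = None,
    rep_sd: float = 0.1,
    n_replicates: int = 3,
    sample_offset_sd: float = 0.3,
    outlier_spec: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a qPCR plate: technical-replicate Cp values per sample/gene.

    Cp decreases one cycle per log2 unit of expression:
    ``Cp = base_cp[gene] - effect[group, gene] + sample_offset + noise``.
    The per-sample offset models plate/loading variation that the
    endogenous-control normalization downstream must cancel.

    ``effects`` maps ``(group, gene)`` to a true log2 effect relative to the
    vehicle group; missing keys mean 0.  The endogenous gene must have effect
    0 in every group.  ``outlier_spec``, if given, is
    ``{"n_outliers": int, "delta": float}``: gross Cp shifts placed at random
    replicate wells and recorded in the truth table.

    Returns ``(cp_table, truth)`` where cp_table has columns
    sample_id, group, gene, replicate, cp.
    """
    genes = list(genes)
    if endogenous_gene not in genes:
        raise ValueError(f"endogenous gene {endogenous_gene!r} missing from design")
    if vehicle_group not in group_sizes:
        raise ValueError(f"vehicle group {vehicle_group!r} missing from design")
    for (g, gene), eff in effects.items():
        if gene == endogenous_gene and eff != 0.0:
            raise ValueError("endogenous gene must have effect 0 in all groups")
    rng = np.random.default_rng([seed, 2])
    base = dict.fromkeys(genes, 24.0)
    base[endogenous_gene] = 20.0
    if base_cp:
        base.update(base_cp)

    rows = []
    for group, n_samples in group_sizes.items():
        for i in range(n_samples):
            sample_id = f"{group}_{i + 1:02d}"
            offset = rng.normal(0.0, sample_offset_sd)
            for gene in genes:
                eff = effects.get((group, gene), 0.0)
                clean = base[gene] - eff + offset
                noise = rng.normal(0.0, rep_sd, size=n_replicates)
                for rep in range(1, n_replicates + 1):
                    rows.append((sample_id, group, gene, rep,
                                 clean + noise[rep - 1], clean, eff))
    truth = pd.DataFrame(rows, columns=[
        "sample_id", "group", "gene", "replicate", "cp",
        "clean_cp", "true_log2_effect"])
    truth["outlier_delta"] = 0.0
    if outlier_spec:
        n_out = int(outlier_spec["n_outliers"])
        delta = float(outlier_spec["delta"])
        hit = rng.choice(len(truth), size=n_out, replace=False)
        truth.loc[hit, "outlier_delta"] = delta
        truth.loc[hit, "cp"] += delta
    truth["outlier_injected"] = truth["outlier_delta"] != 0.0
    cp_table = truth[["sample_id", "group", "gene", "replicate", "cp"]].copy()
    return cp_table, truth


# ---------------------------------------------------------------------------
# Clinical scores

@dataclass(frozen=True)
class GroupScoreProfile:
    """Disease course of one treatment group.

    Defaults follow a chronic EAE experiment: N = 10 animals/group, onset
    around day 12 post-immunization, vehicle animals plateauing near a
    moderate-severe score.
    """

    n_animals: int = 10
    onset_day_mean: float = 12.0
    onset_day_sd: float = 1.5
    plateau: float = 3.5
    plateau_sd: float = 0.5


@dataclass(frozen=True)
class ScoreSimParams:
    """Parameters for clinical-score trajectory simulation (0-6 half-integer
    scale, day grid 0-51 by default, matching a 51-day follow-up)."""

    groups: Mapping[str, GroupScoreProfile] = field(
        default_factory=lambda: {
            "Vehicle": GroupScoreProfile(plateau=3.5),
            "Treated": GroupScoreProfile(plateau=2.0),
        })
    day_range: tuple[int, int] = (0, 51)
    rise_per_day: float = 0.5
    score_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.day_range[0] > self.day_range[1]:
            raise ValueError("day_range must be ordered")


def _snap_half(x: np.ndarray) -> np.ndarray:
    return np.clip(np.round(x * 2.0) / 2.0, 0.0, 6.0)


def simulate_score_trajectories(
    params: ScoreSimParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily clinical scores per animal.

    Zero before onset, then a linear rise (``rise_per_day``) to an
    animal-specific plateau with half-integer measurement noise; a score of
    6 (death) is absorbing — no later observations are emitted.  Animals
    whose drawn plateau is <= 0 stay at score 0 throughout.

    Returns ``(scores, truth)``: scores has columns animal_id, group, day,
    score; truth records each animal's onset day and plateau.
    """
    rng = np.random.default_rng([params.seed, 3])
    days = np.arange(params.day_range[0], params.day_range[1] + 1)
    score_rows = []
    truth_rows = []
    for group, prof in params.groups.items():
        for i in range(prof.n_animals):
            animal = f"{group}_{i + 1:02d}"
            onset = int(round(rng.normal(prof.onset_day_mean,
                                         prof.onset_day_sd)))
            onset = max(onset, params.day_range[0] + 1)
            plateau = prof.plateau
            if prof.plateau_sd > 0:
                plateau = plateau + rng.normal(0.0, prof.plateau_sd)
            plateau = min(plateau, 6.0)
            truth_rows.append((animal, group, onset, max(plateau, 0.0)))
            for day in days:
                if plateau <= 0 or day < onset:
                    score = 0.0
                else:
                    level = min(plateau, (day - onset + 1) * params.rise_per_day)
                    score = float(_snap_half(np.asarray(
                        level + rng.normal(0.0, params.score_noise_sd))))
                score_rows.append((animal, group, int(day), score))
                if score == 6.0:
                    break  # death is absorbing
    scores = pd.DataFrame(score_rows,
                          columns=["animal_id", "group", "day", "score"])
    truth = pd.DataFrame(truth_rows,
                         columns=["animal_id", "group", "onset_day", "plateau"])
    return scores, truth


# ---------------------------------------------------------------------------
# Concordance fixture

def simulate_correlated_log2fc(
    n: int, rho: float, *, scale: float = 0.6, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two log2 fold-change profiles sharing a signature with population
    Pearson correlation ``rho`` (0 < rho < 1).

    Both vectors are ``shared + independent noise`` with the noise variance
    chosen so that corr(A, B) = rho; ``scale`` is the SD of the shared
    signature in log2 units.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    rng = np.random.default_rng([seed, 4])
    shared = rng.normal(0.0, scale, size=n)
    noise_sd = scale * np.sqrt((1.0 - rho) / rho)
    a = shared + rng.normal(0.0, noise_sd, size=n)
    b = shared + rng.normal(0.0, noise_sd, size=n)
    return a, b


def params_from_mapping(mapping: Mapping, cls=SimulationParams):
    """Build a params dataclass from a (possibly partial) mapping, e.g. a
    parsed YAML config; list values for tuple fields are coerced."""
    names = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in mapping.items():
        if key not in names:
            raise ValueError(f"unknown parameter {key!r} for {cls.__name__}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)
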