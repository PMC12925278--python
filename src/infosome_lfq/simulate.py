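"""Synthetic fractionated label-free proteomics experiments with known truth.

The generator emulates the two-group EV study design: a control group and an
inflammasome-activated (treatment) group, three biological replicates each,
the control fractionated into two gel fractions per replicate and the
treatment into four, every fraction injected as two to three technical
replicates.

Generative model, per protein i:

* baseline log2 abundance  b_i ~ Normal(baseline_log2_mean, baseline_log2_sd);
* a fixed fraction of proteins is "spiked" with a true effect of magnitude
  ``spike_log2fc``, sign randomized 50/50; treatment biological-replicate
  abundance is 2^(b_i + effect_i), control is 2^(b_i);
* the replicate's linear-scale abundance is apportioned across its fractions
  by a Dirichlet draw (concentration ``fraction_split``), so summing fraction
  values recovers the replicate total exactly — the pipeline's sum-across-
  fractions rule is the exact inverse of the generative split;
* each technical replicate multiplies the fraction value by lognormal noise
  with coefficient of variation ``tech_cv``;
* each run-level cell then goes missing with probability
  ``mnar_max * expit(-mnar_slope * (log2 intensity - mnar_midpoint))``
  (intensity-dependent non-detection) and additionally, independently, with
  probability ``mcar_rate``.

Identification evidence is drawn so that a configurable fraction of proteins
independently fails each stringency criterion (probability, unique peptides,
spectral counts). Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import ID_COLUMNS, QuantMatrix, RunDesign

__all__ = ["GroupDesign", "SimulationConfig", "SimulationTruth", "SimulatedExperiment",
           "simulate", "evaluate_recovery"]


@dataclass(frozen=True)
class GroupDesign:
    """One experimental group: label, biological replicates, fractions, injections."""

    label: str
    n_bio_reps: int = 3
    n_fractions: int = 2
    n_tech_reps: int = 2


def _default_groups() -> tuple[GroupDesign, ...]:
    # mirrors the EV study: control 2 fractions, treatment 4; 2-3 injections
    return (
        GroupDesign("Control", n_bio_reps=3, n_fractions=2, n_tech_reps=2),
        GroupDesign("LN", n_bio_reps=3, n_fractions=4, n_tech_reps=3),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    The first group is the control (zero effect); every later group carries
    the spiked effects. Rates are probabilities in [0, 1]; ``tech_cv`` is the
    technical coefficient of variation of a single injection.
    """

    n_proteins: int = 2000
    groups: tuple[GroupDesign, ...] = field(default_factory=_default_groups)
    baseline_log2_mean: float = 22.0
    baseline_log2_sd: float = 2.0
    spike_fraction: float = 0.10
    spike_log2fc: float = 2.0
    fraction_split: float = 2.0     # Dirichlet concentration per fraction
    tech_cv: float = 0.2
    mnar_midpoint: float = 17.5     # log2 intensity of half-maximal dropout
    mnar_slope: float = 0.9
    mnar_max: float = 0.6           # dropout probability asymptote at low intensity
    mcar_rate: float = 0.02
    id_fail_rate: float = 0.05      # per stringency criterion
    seed: int = 0

    def validate(self) -> None:
        bad = []
        if self.n_proteins < 1:
            bad.append("n_proteins")
        if len(self.groups) < 2:
            bad.append("groups (need >= 2)")
        for g in self.groups:
            if g.n_bio_reps < 1 or g.n_fractions < 1 or g.n_tech_reps < 1:
                bad.append(f"groups[{g.label}]")
        if self.baseline_log2_sd <= 0:
            bad.append("baseline_log2_sd")
        for name in ("spike_fraction", "mnar_max", "mcar_rate", "id_fail_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                bad.append(name)
        if self.tech_cv <= 0:
            bad.append("tech_cv")
        if self.fraction_split <= 0:
            bad.append("fraction_split")
        if self.mnar_slope < 0:
            bad.append("mnar_slope")
        if bad:
            raise ValueError(f"invalid simulation config fields: {bad}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated experiment.

    ``proteins`` has per-protein true_log2fc and spiked flag; ``biorep_log2``
    is the noise-free biological-replicate log2 abundance; ``fraction_values``
    the exact linear-scale Dirichlet split (its within-replicate sum equals
    2^biorep_log2); ``run_intensities`` the post-noise, pre-missingness run
    matrix.
    """

    proteins: pd.DataFrame
    biorep_log2: pd.DataFrame
    fraction_values: pd.DataFrame
    run_intensities: pd.DataFrame


@dataclass(frozen=True)
class SimulatedExperiment:
    matrix: QuantMatrix
    design: RunDesign
    id_records: pd.DataFrame
    truth: SimulationTruth
    config: SimulationConfig


def simulate(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one experiment (run matrix, design, identification table, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    ids = [f"P{i + 1:05d}" for i in range(n)]

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    n_spiked = int(round(config.spike_fraction * n))
    spiked_idx = rng.choice(n, size=n_spiked, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_spiked)
    true_lfc = np.zeros(n)
    true_lfc[spiked_idx] = signs * config.spike_log2fc
    spiked = np.zeros(n, dtype=bool)
    spiked[spiked_idx] = True

    design_rows = []
    biorep_cols: dict[tuple[str, str], np.ndarray] = {}
    frac_cols: dict[tuple[str, str, int], np.ndarray] = {}
    run_cols: dict[str, np.ndarray] = {}
    obs_cols: dict[str, np.ndarray] = {}

    for gi, g in enumerate(config.groups):
        effect = true_lfc if gi > 0 else 0.0
        for r in range(1, g.n_bio_reps + 1):
            rep = f"r{r}"
            biorep_log2 = baseline + effect
            total = 2.0 ** biorep_log2
            biorep_cols[(g.label, rep)] = biorep_log2
            # linear-scale Dirichlet apportionment across fractions
            split = rng.dirichlet(np.full(g.n_fractions, config.fraction_split), size=n)
            frac_vals = total[:, None] * split
            sigma = np.sqrt(np.log1p(config.tech_cv**2))
            for f in range(1, g.n_fractions + 1):
                fv = frac_vals[:, f - 1]
                frac_cols[(g.label, rep, f)] = fv
                for t in range(1, g.n_tech_reps + 1):
                    run_id = f"{g.label}_{rep}_f{f}_t{t}"
                    design_rows.append((run_id, g.label, rep, f, t))
                    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
                    v = fv * noise
                    run_cols[run_id] = v
                    p_mnar = config.mnar_max * expit(
                        -config.mnar_slope * (np.log2(v) - config.mnar_midpoint)
                    )
                    miss = rng.random(n) < p_mnar
                    miss |= rng.random(n) < config.mcar_rate
                    obs = v.copy()
                    obs[miss] = np.nan
                    obs_cols[run_id] = obs

    design = RunDesign(pd.DataFrame(design_rows, columns=["run_id", "group", "bio_rep",
                                                          "fraction", "tech_rep"]))
    matrix = QuantMatrix(pd.DataFrame(obs_cols, index=ids), level="run")

    id_records = _simulate_identifications(rng, ids, config.id_fail_rate)
    truth = SimulationTruth(
        proteins=pd.DataFrame({"protein_id": ids, "true_log2fc": true_lfc,
                               "spiked": spiked}),
        biorep_log2=pd.DataFrame(
            biorep_cols, index=ids
        ).set_axis(pd.MultiIndex.from_tuples(biorep_cols, names=["group", "bio_rep"]),
                   axis=1),
        fraction_values=pd.DataFrame(
            frac_cols, index=ids
        ).set_axis(pd.MultiIndex.from_tuples(frac_cols,
                                             names=["group", "bio_rep", "fraction"]),
                   axis=1),
        run_intensities=pd.DataFrame(run_cols, index=ids),
    )
    return SimulatedExperiment(matrix=matrix, design=design, id_records=id_records,
                               truth=truth, config=config)


def _simulate_identifications(rng: np.random.Generator, ids: list[str],
                              fail_rate: float) -> pd.DataFrame:
    """Per-protein search evidence; each stringency criterion fails independently."""
    n = len(ids)
    prob = 1.0 - rng.beta(1.0, 200.0, size=n) * 0.01       # bulk well above 0.99
    fail_prob = rng.random(n) < fail_rate
    prob[fail_prob] = rng.uniform(0.80, 0.99, size=fail_prob.sum())
    unique_peptides = 2 + rng.poisson(4.0, size=n)
    fail_pep = rng.random(n) < fail_rate
    unique_peptides[fail_pep] = 1
    unique_spectra = np.maximum(unique_peptides, 2) + rng.poisson(3.0, size=n)
    fail_spec = rng.random(n) < fail_rate
    unique_spectra[fail_spec] = 1
    total_spectra = unique_spectra + rng.poisson(5.0, size=n)
    return pd.DataFrame(
        dict(zip(ID_COLUMNS, [ids, prob, unique_peptides, total_spectra, unique_spectra]))
    )


def evaluate_recovery(results: pd.DataFrame, truth: SimulationTruth) -> dict[str, float]:
    """Score a differential-result table against the simulation truth.

    * sensitivity — fraction of spiked proteins called in the correct
      direction (a spiked protein absent from the results, e.g. removed by a
      filter, counts as missed);
    * specificity — fraction of tested null proteins called 'ns';
    * fc_bias / fc_rmse — mean error and root-mean-square error of estimated
      vs true log2 fold change over tested spiked proteins.
    """
    tp = truth.proteins.set_index("protein_id")
    res = results.set_index("protein_id")
    unknown = res.index.difference(tp.index)
    if len(unknown):
        raise ValueError(f"result proteins absent from truth: {unknown.tolist()}")

    spiked = tp.index[tp["spiked"]]
    tested_spiked = spiked.intersection(res.index)
    correct = 0
    for pid in tested_spiked:
        want = "up" if tp.loc[pid, "true_log2fc"] > 0 else "down"
        if res.loc[pid, "status"] == want:
            correct += 1
    sensitivity = correct / len(spiked) if len(spiked) else float("nan")

    nulls = tp.index[~tp["spiked"]]
    tested_nulls = nulls.intersection(res.index)
    if len(tested_nulls):
        specificity = float((res.loc[tested_nulls, "status"] == "ns").mean())
    else:
        specificity = float("nan")

    if len(tested_spiked):
        err = (res.loc[tested_spiked, "log2fc"]
               - tp.loc[tested_spiked, "true_log2fc"]).to_numpy()
        fc_bias = float(err.mean())
        fc_rmse = float(np.sqrt((err**2).mean()))
    else:
        fc_bias = fc_rmse = float("nan")
    return {"sensitivity": sensitivity, "specificity": specificity,
            "fc_bias": fc_bias, "fc_rmse": fc_rmse}
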