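"""Synthetic-data generators with planted ground truth.

Every downstream stage of the pipeline (viability normalization, synergy
scoring, differential expression, survival screening, overlap) is testable
against data produced here, because each generator records exactly what it
planted:

* :func:`simulate_plate` — CCK8-style optical-density plates whose treated
  wells follow a Hill dose-response curve.
* :func:`simulate_combination_grid` — single-agent plates plus a combination
  plate whose true combined killing effect deviates from the Bliss
  independence expectation by a known multiplier ``psi``; ``psi`` is the
  exact recovery target for the combination index Q.
* :func:`simulate_survival_cohort` — a TCGA/Xena-like expression matrix on a
  log2(FPKM+1)-like scale with right-censored survival times drawn from a
  proportional-hazards model in which a known subset of genes carries a
  nonzero log-hazard effect.
* :func:`simulate_counts` — negative-binomial RNA-seq count matrices with a
  known subset of differentially expressed genes at a fixed log2 fold change.

All generators are pure functions of their spec plus a seed: identical
inputs give bitwise-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HillCurve",
    "CombinationScenario",
    "SurvivalSimSpec",
    "CountSimSpec",
    "CombinationGrid",
    "simulate_plate",
    "simulate_combination_grid",
    "simulate_survival_cohort",
    "simulate_two_group_cohort",
    "simulate_counts",
]

# OD model: od = blank + span * viability + noise, with span fixed at 1.0.
# The simplest model that still exercises blank/control normalization.
_OD_SPAN = 1.0
_DEFAULT_BLANK_OD = 0.05  # typical CCK8 background absorbance


@dataclass(frozen=True)
class HillCurve:
    """Single-agent dose-response: killing-effect fraction as a Hill function.

    effect(d) = emax * d^h / (ec50^h + d^h)

    Parameters
    ----------
    emax : float
        Maximal killing-effect fraction, in [0, 1].
    ec50 : float
        Dose at half-maximal effect (same units as the dose axis), > 0.
    h : float
        Hill coefficient, > 0.
    """

    emax: float
    ec50: float
    h: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.emax <= 1.0:
            raise ValueError(f"emax must be in [0, 1], got {self.emax}")
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.h <= 0:
            raise ValueError(f"h must be > 0, got {self.h}")

    def effect(self, dose) -> np.ndarray:
        """Killing-effect fraction at ``dose`` (0 at dose 0, non-decreasing)."""
        d = np.asarray(dose, dtype=float)
        if np.any(d < 0):
            raise ValueError("dose must be non-negative")
        with np.errstate(divide="ignore"):
            dh = np.where(d > 0, d, np.nan) ** self.h
        eff = np.where(d > 0, self.emax * dh / (self.ec50**self.h + dh), 0.0)
        return eff if eff.ndim else float(eff)


@dataclass(frozen=True)
class CombinationScenario:
    """Ground truth for a two-drug combination experiment.

    ``psi`` multiplies the Bliss independence expectation
    KEa + KEb - KEa*KEb; psi = 1 yields exact Bliss additivity (downstream
    Q = 1 at every dose pair on noise-free data), psi > 1 synergy,
    psi < 1 antagonism. The generated combined killing effect is clipped
    to [0, 1].
    """

    drug_a: HillCurve
    drug_b: HillCurve
    psi: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psi <= 0:
            raise ValueError(f"psi must be > 0, got {self.psi}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")

    def true_combined_ke(self, dose_a, dose_b) -> np.ndarray:
        """Noise-free combined killing effect: clip(psi * Bliss, 0, 1)."""
        kea = np.asarray(self.drug_a.effect(dose_a), dtype=float)
        keb = np.asarray(self.drug_b.effect(dose_b), dtype=float)
        bliss = kea + keb - kea * keb
        return np.clip(self.psi * bliss, 0.0, 1.0)


@dataclass(frozen=True)
class SurvivalSimSpec:
    """Spec for a synthetic expression + survival cohort.

    Defaults emulate a desk-scale TCGA-like cohort: 400 patients, 500 genes
    of which ~1.6% are truly prognostic (per-unit log-hazard ln 3 on the
    standardized expression scale), baseline hazard set so that median
    survival is five years (ln 2 / 1825 per day), light independent
    censoring, ten-year administrative horizon.
    """

    n_samples: int = 400
    n_genes: int = 500
    frac_prognostic: float = 0.016
    beta: float = math.log(3.0)
    baseline_hazard: float = math.log(2.0) / 1825.0  # per day
    censor_rate: float = 1e-4  # per day
    horizon: float = 3650.0  # days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not 0.0 <= self.frac_prognostic <= 1.0:
            raise ValueError("frac_prognostic must be in [0, 1]")
        if self.baseline_hazard < 0 or self.censor_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.horizon <= 0:
            raise ValueError(f"horizon must be > 0, got {self.horizon}")


@dataclass(frozen=True)
class CountSimSpec:
    """Spec for a two-group negative-binomial count matrix.

    ``dispersion`` is the NB dispersion (variance = mu + dispersion * mu^2);
    0 gives Poisson counts. Planted DE genes have a between-group mean ratio
    of exactly 2**lfc_magnitude, half up- and half down-regulated unless
    directions are overridden. n_per_group defaults to 3 (typical minimal
    replication for a 3'-mRNA-seq screen).
    """

    n_genes: int = 2000
    n_per_group: int = 3
    lib_size: float = 1_000_000.0
    dispersion: float = 0.05
    frac_de: float = 0.1
    lfc_magnitude: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.dispersion < 0:
            raise ValueError(f"dispersion must be >= 0, got {self.dispersion}")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must be in [0, 1]")
        if self.lib_size <= 0:
            raise ValueError("lib_size must be > 0")


def _well_rows(role: str, drug: str, dose, n: int, start: int):
    return [
        {"well": f"{role[0].upper()}{start + i}", "role": role, "drug": drug,
         "dose": dose, "replicate": i + 1}
        for i in range(n)
    ]


def simulate_plate(
    curve: HillCurve,
    doses,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    drug: str = "drug",
    blank_od: float = _DEFAULT_BLANK_OD,
) -> pd.DataFrame:
    """Simulate a CCK8 viability plate for one drug.

    Returns a tidy frame with columns ``well, role, drug, dose, replicate,
    od``. Blank wells carry no signal above background; control (untreated)
    wells have expected normalized viability 1; treated wells have expected
    viability ``1 - curve.effect(dose)``. Gaussian noise of scale
    ``noise_sd`` is added to every optical density.
    """
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rows = _well_rows("blank", "", np.nan, replicates, 1)
    rows += _well_rows("control", drug, 0.0, replicates, 1)
    for j, d in enumerate(doses):
        rows += _well_rows("treated", drug, float(d), replicates, 1)
        for r in rows[-replicates:]:
            r["well"] = f"T{j + 1}-{r['replicate']}"
    plate = pd.DataFrame(rows)

    viab = np.ones(len(plate))
    treated = plate["role"] == "treated"
    viab[treated.to_numpy()] = 1.0 - np.asarray(
        curve.effect(plate.loc[treated, "dose"].to_numpy())
    )
    viab[(plate["role"] == "blank").to_numpy()] = 0.0

    rng = np.random.default_rng(seed)
    od = blank_od + _OD_SPAN * viab + rng.normal(0.0, noise_sd, len(plate))
    plate["od"] = od
    return plate


@dataclass(frozen=True)
class CombinationGrid:
    """Three plates from one combination experiment plus their scenario."""

    scenario: CombinationScenario
    plate_a: pd.DataFrame
    plate_b: pd.DataFrame
    plate_ab: pd.DataFrame  # columns well, role, drug, dose_a, dose_b, replicate, od


def simulate_combination_grid(
    scenario: CombinationScenario,
    doses_a,
    doses_b,
    replicates: int = 3,
    *,
    blank_od: float = _DEFAULT_BLANK_OD,
) -> CombinationGrid:
    """Simulate single-agent plates for drugs a and b plus the a+b grid.

    The combination plate covers the full ``doses_a x doses_b`` product grid;
    its noise-free combined killing effect is
    ``clip(psi * (KEa + KEb - KEa*KEb), 0, 1)``. Seeds for the three plates
    are derived deterministically from ``scenario.seed``.
    """
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if doses_a.size == 0 or doses_b.size == 0:
        raise ValueError("dose grids must be non-empty")
    if np.any(doses_a < 0) or np.any(doses_b < 0):
        raise ValueError("doses must be non-negative")

    seeds = np.random.default_rng(scenario.seed).integers(0, 2**31 - 1, 3)
    plate_a = simulate_plate(
        scenario.drug_a, doses_a, replicates, scenario.noise_sd,
        seed=int(seeds[0]), drug="a", blank_od=blank_od,
    )
    plate_b = simulate_plate(
        scenario.drug_b, doses_b, replicates, scenario.noise_sd,
        seed=int(seeds[1]), drug="b", blank_od=blank_od,
    )

    rng = np.random.default_rng(int(seeds[2]))
    rows = []
    for i in range(replicates):
        rows.append({"well": f"B{i+1}", "role": "blank", "drug": "",
                     "dose_a": np.nan, "dose_b": np.nan, "replicate": i + 1,
                     "viab": 0.0})
        rows.append({"well": f"C{i+1}", "role": "control", "drug": "a+b",
                     "dose_a": 0.0, "dose_b": 0.0, "replicate": i + 1,
                     "viab": 1.0})
    for da in doses_a:
        for db in doses_b:
            ke = float(scenario.true_combined_ke(da, db))
            for i in range(replicates):
                rows.append({"well": f"T{da}x{db}-{i+1}", "role": "treated",
                             "drug": "a+b", "dose_a": float(da),
                             "dose_b": float(db), "replicate": i + 1,
                             "viab": 1.0 - ke})
    plate_ab = pd.DataFrame(rows)
    plate_ab["od"] = (
        blank_od
        + _OD_SPAN * plate_ab.pop("viab")
        + rng.normal(0.0, scenario.noise_sd, len(plate_ab))
    )
    return CombinationGrid(scenario, plate_a, plate_b, plate_ab)


# expression offset placing centered N(0,1) values on a log2(FPKM+1)-like
# non-negative scale; hazards always use the centered value
_EXPR_OFFSET = 6.0


def simulate_survival_cohort(
    spec: SurvivalSimSpec,
    *,
    prognostic_index=None,
    prognostic_sign=None,
):
    """Simulate an expression matrix plus right-censored survival table.

    Gene expression is drawn i.i.d. standard normal per gene and shifted to
    a non-negative log2(FPKM+1)-like scale. Event times follow a
    proportional-hazards model whose per-sample hazard is
    ``baseline_hazard * exp(sum_g sign_g * beta * z_g)`` over the planted
    prognostic genes (z is the centered expression). Censoring is an
    independent exponential clock plus administrative censoring at
    ``horizon``.

    Parameters
    ----------
    prognostic_index, prognostic_sign : array-like, optional
        Explicit planted gene positions and their effect signs (+1 hazardous,
        -1 protective). By default the first ``round(frac_prognostic *
        n_genes)`` genes are planted with alternating signs.

    Returns
    -------
    expr : DataFrame, genes x samples, non-negative
    surv : DataFrame with columns ``sample, time, event``
    truth : DataFrame with columns ``gene, prognostic, beta`` (signed)
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]

    z = rng.standard_normal((spec.n_genes, spec.n_samples))
    expr = np.clip(z + _EXPR_OFFSET, 0.0, None)

    if prognostic_index is None:
        k = int(round(spec.frac_prognostic * spec.n_genes))
        prognostic_index = np.arange(k)
        prognostic_sign = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    prognostic_index = np.asarray(prognostic_index, dtype=int)
    prognostic_sign = np.asarray(prognostic_sign, dtype=float)
    if prognostic_index.shape != prognostic_sign.shape:
        raise ValueError("prognostic_index and prognostic_sign must align")

    beta_vec = np.zeros(spec.n_genes)
    beta_vec[prognostic_index] = prognostic_sign * spec.beta

    log_hazard = beta_vec @ z  # centered values drive the hazard
    hazard = spec.baseline_hazard * np.exp(log_hazard)
    draws = rng.exponential(1.0, spec.n_samples)
    with np.errstate(divide="ignore"):
        event_time = np.where(hazard > 0, draws / np.where(hazard > 0, hazard, 1.0), np.inf)
    if spec.censor_rate > 0:
        censor_time = rng.exponential(1.0 / spec.censor_rate, spec.n_samples)
    else:
        censor_time = np.full(spec.n_samples, np.inf)
    limit = np.minimum(censor_time, spec.horizon)
    time = np.minimum(event_time, limit)
    event = (event_time <= limit).astype(int)
    # guard against zero observed time (degenerate for rank-based statistics)
    time = np.maximum(time, 1e-9)

    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    surv_df = pd.DataFrame({"sample": samples, "time": time, "event": event})
    truth = pd.DataFrame({
        "gene": genes,
        "prognostic": beta_vec != 0,
        "beta": beta_vec,
    })
    return expr_df, surv_df, truth


def simulate_two_group_cohort(
    n_samples: int,
    hr: float,
    baseline_hazard: float = math.log(2.0) / 1825.0,
    censor_rate: float = 1e-4,
    horizon: float = 3650.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Two-arm proportional-hazards cohort with a known hazard ratio.

    Convenience generator for calibration studies: samples are assigned
    50/50 to ``group`` 0/1 and the hazard of group 1 is ``hr`` times the
    baseline. Returns columns ``sample, time, event, group``.
    """
    if hr <= 0:
        raise ValueError("hr must be > 0")
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    rng = np.random.default_rng(seed)
    group = (rng.random(n_samples) < 0.5).astype(int)
    hazard = baseline_hazard * hr**group
    event_time = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        censor_time = rng.exponential(1.0 / censor_rate, n_samples)
    else:
        censor_time = np.full(n_samples, np.inf)
    limit = np.minimum(censor_time, horizon)
    time = np.maximum(np.minimum(event_time, limit), 1e-9)
    event = (event_time <= limit).astype(int)
    return pd.DataFrame({
        "sample": [f"S{i:04d}" for i in range(n_samples)],
        "time": time,
        "event": event,
        "group": group,
    })


def simulate_counts(spec: CountSimSpec, *, de_index=None, de_sign=None):
    """Simulate a two-group negative-binomial count matrix.

    Gene relative abundances are log-normal; within each group, gene means
    are gamma-mixed Poisson (i.e. negative binomial with the spec's
    dispersion). Planted DE genes have a treated/untreated mean ratio of
    exactly ``2**lfc_magnitude`` (sign +1) or ``2**-lfc_magnitude``
    (sign -1).

    Returns
    -------
    counts : DataFrame, genes x samples (integer)
    groups : Series mapping sample id -> {"untreated", "treated"}
    truth : DataFrame with columns ``gene, de, lfc`` (signed log2 ratio)
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    n = spec.n_per_group
    samples = [f"U{i+1}" for i in range(n)] + [f"T{i+1}" for i in range(n)]
    group = np.array(["untreated"] * n + ["treated"] * n)

    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    base_mu = abundance / abundance.sum() * spec.lib_size

    if de_index is None:
        k = int(round(spec.frac_de * spec.n_genes))
        de_index = np.arange(k)
        de_sign = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    de_index = np.asarray(de_index, dtype=int)
    de_sign = np.asarray(de_sign, dtype=float)
    if de_index.shape != de_sign.shape:
        raise ValueError("de_index and de_sign must align")

    lfc = np.zeros(spec.n_genes)
    lfc[de_index] = de_sign * spec.lfc_magnitude

    mu = np.tile(base_mu[:, None], (1, 2 * n)).astype(float)
    mu[:, n:] *= 2.0**lfc[:, None]

    if spec.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, mu * spec.dispersion)
        counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    groups = pd.Series(group, index=samples, name="group")
    truth = pd.DataFrame({"gene": genes, "de": lfc != 0, "lfc": lfc})
    return counts_df, groups, truth
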