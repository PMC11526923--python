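"""Synthetic cohort generator with known ground truth.

Generates a genotype panel with block-structured (breed-like) allele
frequencies plus admixed dogs, and a metabolite panel with the statistical
structure every downstream stage assumes:

    y_j = Z beta_j + b_j * M + d_j * z_age + u_j + eps_j

with u_j ~ MVN(0, h2_j * K), var(u_j) + var(eps_j) = 1, and the mediator
M = a * z_age + noise written to the cohort as a creatinine-like column.
Raw intensities are built on the log scale -- clean signal plus per-sample
shifts, per-batch intercept and run-order drift, optional technical-covariate
effects -- and then exponentiated, so the preprocessing ledger can undo them.

The mediator noise is Gaussian and independent of the polygenic term, so the
product of coefficients a*b is exact ground truth for the mediation module,
and the true proportion mediated is a*b / (a*b + d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix
from .lmm import build_design, life_stage
from .preprocess import MetaboliteMatrix

DIET_LEVELS = ("kibble", "canned", "home_cooked", "raw_commercial")
DIET_PROBS = (0.86, 0.04, 0.05, 0.05)


@dataclass
class MediatorSpec:
    """Linear mediator chain: age -> mediator -> metabolite.

    ``a`` is the effect of (standardized sqrt) age on the mediator, ``sigma_m``
    the mediator residual SD, and ``targets`` maps metabolite index to its
    (b, d) pair: mediator -> metabolite slope and direct age -> metabolite
    slope.  True ACME is a*b and true proportion mediated a*b / (a*b + d).
    """

    a: float = 0.5
    sigma_m: float = 1.0
    targets: dict[int, tuple[float, float]] = field(default_factory=dict)


@dataclass
class DriftSpec:
    """Batch intercepts and within-batch run-order slopes on the log scale."""

    intercept_sd: float = 0.5
    slope_sd: float = 0.03


@dataclass
class SimulationConfig:
    n_dogs: int = 784
    n_metabolites: int = 137
    n_snps: int = 5000
    n_breed_blocks: int = 8
    admixed_fraction: float = 0.6
    age_range: tuple[float, float] = (0.7, 18.0)
    batch_size: int = 40
    n_runs: int = 5
    effect_table: pd.DataFrame | None = None  # metabolite x covariate true betas
    h2_table: np.ndarray | None = None  # per-metabolite true heritability
    mediator_spec: MediatorSpec = field(default_factory=MediatorSpec)
    drift_spec: DriftSpec = field(default_factory=DriftSpec)
    missing_rate: float = 0.03
    hemolysis_rates: tuple[float, ...] = (0.80, 0.10, 0.05, 0.03, 0.02)
    contamination: bool = False
    contamination_shift: float = 2.0
    n_cbc: int = 17
    n_corr_block: int = 0  # planted residual-correlated metabolite block
    corr_block_loading: float = 0.6
    fst: float = 0.15
    sample_shift_sd: float = 0.3
    tech_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must satisfy min < max")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if abs(sum(self.hemolysis_rates) - 1.0) > 1e-9:
            raise ValueError("hemolysis_rates must sum to 1")
        if not 0.0 <= self.admixed_fraction <= 1.0:
            raise ValueError("admixed_fraction must lie in [0, 1]")
        if self.h2_table is not None:
            h2 = np.asarray(self.h2_table, dtype=float)
            if ((h2 < 0) | (h2 >= 1)).any():
                raise ValueError("h2 values must lie in [0, 1)")
            self.h2_table = h2


@dataclass
class GroundTruth:
    true_beta: pd.DataFrame  # metabolite x covariate (age column = total effect)
    true_h2: np.ndarray
    true_acme: np.ndarray
    true_prop_mediated: np.ndarray  # NaN where total age effect is 0
    breeding_values: pd.DataFrame  # dogs x metabolites
    latent: pd.DataFrame  # drift-free log-scale signal (dogs x metabolites)
    drift_intercepts: np.ndarray  # batches x metabolites
    drift_slopes: np.ndarray


def _met_names(n: int) -> list[str]:
    return [f"met_{i:03d}" for i in range(n)]


def _dog_ids(n: int) -> list[str]:
    return [f"dog_{i:04d}" for i in range(n)]


def default_effect_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sparse true fixed effects: 40 age, 20 weight, 10 sex, a few diet contrasts."""
    m = config.n_metabolites
    cols = ["sqrt_age", "sqrt_weight", "sex", "sterilized", "fasting"] + [
        f"diet[{lv}]" for lv in DIET_LEVELS[1:]
    ]
    beta = pd.DataFrame(np.zeros((m, len(cols))), index=_met_names(m), columns=cols)
    n_age = min(40, m)
    age_idx = rng.choice(m, size=n_age, replace=False)
    beta.iloc[age_idx, 0] = rng.uniform(0.2, 0.5, n_age) * rng.choice([-1, 1], n_age)
    n_w = min(20, m)
    w_idx = rng.choice(m, size=n_w, replace=False)
    beta.iloc[w_idx, 1] = rng.uniform(0.1, 0.3, n_w) * rng.choice([-1, 1], n_w)
    n_s = min(10, m)
    s_idx = rng.choice(m, size=n_s, replace=False)
    beta.iloc[s_idx, 2] = rng.uniform(0.1, 0.3, n_s) * rng.choice([-1, 1], n_s)
    if m >= 3:
        beta.iloc[rng.choice(m, 2, replace=False), beta.columns.get_loc("diet[raw_commercial]")] = -0.49
    return beta


def default_h2_table(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.uniform(0.0, 0.6, config.n_metabolites)


def default_mediator_spec(config: SimulationConfig, rng: np.random.Generator) -> MediatorSpec:
    """Seven mediator-chain metabolites, six truly mediated, one direct-only."""
    m = config.n_metabolites
    n_chain = min(7, m)
    idx = rng.choice(m, size=n_chain, replace=False)
    targets: dict[int, tuple[float, float]] = {}
    for rank, j in enumerate(idx):
        if rank < n_chain - 1:
            targets[int(j)] = (0.6, 0.3)  # mediated: prop = a*b/(a*b+d)
        else:
            targets[int(j)] = (0.0, 0.45)  # age effect without mediation
    return MediatorSpec(a=0.7, sigma_m=1.0, targets=targets)


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Block-structured dosage matrix (dogs x SNPs) and ancestry proportions.

    Allele frequencies per breed block follow a Balding-Nichols draw around a
    shared ancestral frequency; admixed dogs mix block frequencies with
    Dirichlet weights.  SNPs failing MAF > 1% after generation are redrawn.
    """
    if config.n_breed_blocks < 1:
        raise ValueError("n_breed_blocks must be >= 1")
    if config.n_snps < 100:
        raise ValueError("n_snps must be >= 100")
    if config.n_dogs < 2 * config.n_breed_blocks:
        raise ValueError(
            f"degenerate config: n_dogs={config.n_dogs} < "
            f"2 * n_breed_blocks={2 * config.n_breed_blocks}"
        )
    rng = np.random.default_rng((config.seed, 0xA))
    nb, ns, nd = config.n_breed_blocks, config.n_snps, config.n_dogs
    breeds = [f"breed_{b:02d}" for b in range(nb)]

    n_admixed = int(round(nd * config.admixed_fraction))
    n_pure = nd - n_admixed
    W = np.zeros((nd, nb))
    pure_block = np.arange(n_pure) % nb
    W[np.arange(n_pure), pure_block] = 1.0
    if n_admixed:
        if nb < 2:
            raise ValueError("admixed dogs require n_breed_blocks >= 2")
        W[n_pure:] = rng.dirichlet(np.full(nb, 0.5), size=n_admixed)

    def draw_freqs(k: int) -> np.ndarray:
        anc = rng.uniform(0.1, 0.9, k)
        f = config.fst
        shape = (1.0 - f) / f
        return rng.beta(anc * shape, (1.0 - anc) * shape, size=(nb, k)).T  # k x nb

    P = draw_freqs(ns)  # snp x block
    G = np.empty((nd, ns))
    todo = np.arange(ns)
    for _ in range(100):
        p_dog = W @ P[todo].T  # dogs x |todo|
        G[:, todo] = rng.binomial(2, np.clip(p_dog, 0.0, 1.0))
        maf = np.minimum(G[:, todo].mean(axis=0) / 2, 1 - G[:, todo].mean(axis=0) / 2)
        fail = maf <= 0.01
        if not fail.any():
            break
        P[todo[fail]] = draw_freqs(int(fail.sum()))
        todo = todo[fail]
    else:  # pragma: no cover
        raise RuntimeError("could not generate SNPs passing the MAF filter")

    ids = _dog_ids(nd)
    genotypes = pd.DataFrame(G, index=ids, columns=[f"snp_{k:05d}" for k in range(ns)])
    ancestry = pd.DataFrame(W, index=ids, columns=breeds)
    return genotypes, ancestry


def _kinship_root(K: KinshipMatrix) -> np.ndarray:
    d, U = np.linalg.eigh(K.K)
    if d.min() < -1e-8 * max(d.max(), 1.0):
        raise ValueError(f"kinship matrix is not PSD (min eigenvalue {d.min():.3g})")
    return U * np.sqrt(np.maximum(d, 0.0))


def simulate_phenotypes(
    config: SimulationConfig,
    genotypes: pd.DataFrame,
    kin: KinshipMatrix,
) -> tuple[MetaboliteMatrix, pd.DataFrame, GroundTruth]:
    """Raw metabolite matrix, cohort covariate table and ground truth."""
    rng = np.random.default_rng((config.seed, 0xB))
    nd, m = config.n_dogs, config.n_metabolites
    if kin.n != nd:
        raise ValueError(f"kinship is {kin.n} dogs, config says {nd}")
    ids = list(kin.dog_ids)
    mets = _met_names(m)
    A = _kinship_root(kin)

    # --- cohort covariates -------------------------------------------------
    age = rng.uniform(*config.age_range, nd)
    weight = np.exp(rng.normal(np.log(20.0), 0.6, nd)).round(1)
    sex = rng.integers(0, 2, nd)
    sterilized = (rng.random(nd) < 0.87).astype(int)
    fasting = np.round(rng.uniform(4, 18, nd))
    diet = rng.choice(DIET_LEVELS, size=nd, p=DIET_PROBS)
    cohort = pd.DataFrame(
        {
            "age": age,
            "weight": weight,
            "sex": sex,
            "sterilized": sterilized,
            "fasting": fasting,
            "diet": diet,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    cohort["life_stage"] = life_stage(cohort["age"]).astype(str)
    for c in range(config.n_cbc):
        cohort[f"cbc_{c:02d}"] = rng.normal(0.0, 1.0, nd)

    z_age = (np.sqrt(age) - np.sqrt(age).mean()) / np.sqrt(age).std(ddof=1)
    med = config.mediator_spec
    mediator = med.a * z_age + rng.normal(0.0, med.sigma_m, nd)
    cohort["creatinine"] = mediator
    cohort["bun"] = 0.5 * mediator + rng.normal(0.0, 1.0, nd)

    # --- true fixed effects ------------------------------------------------
    beta = config.effect_table
    if beta is None:
        beta = default_effect_table(config, rng)
    beta = beta.reindex(index=mets).fillna(0.0)
    h2 = config.h2_table
    if h2 is None:
        h2 = default_h2_table(config, rng)
    h2 = np.asarray(h2, dtype=float)
    if h2.shape != (m,):
        raise ValueError(f"h2_table must have length {m}")

    design = build_design(
        cohort,
        cbc_cols=[],
        interactions=(),
        diet_reference=DIET_LEVELS[0] if len(set(diet)) > 1 else None,
        standardize_numeric=True,
    )
    Z = design.X.drop(columns="(Intercept)")
    B = beta.reindex(columns=Z.columns).fillna(0.0).to_numpy().T  # covariate x met
    signal = Z.to_numpy() @ B

    # --- polygenic + mediator + noise -------------------------------------
    bv = (A @ rng.standard_normal((nd, m))) * np.sqrt(h2)
    eps = rng.standard_normal((nd, m)) * np.sqrt(1.0 - h2)
    y = signal + bv + eps
    acme = np.zeros(m)
    direct = np.zeros(m)
    for j, (b_j, d_j) in med.targets.items():
        y[:, j] += b_j * mediator + d_j * z_age
        acme[j] = med.a * b_j
        direct[j] = d_j
    if config.n_corr_block:
        factor = rng.standard_normal(nd)
        y[:, : config.n_corr_block] += config.corr_block_loading * factor[:, None]

    total_age = beta.reindex(columns=Z.columns).fillna(0.0)["sqrt_age"].to_numpy() + acme + direct
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(total_age != 0.0, acme / total_age, np.nan)
    true_beta = beta.reindex(columns=Z.columns).fillna(0.0).copy()
    true_beta["sqrt_age"] = total_age

    latent = pd.DataFrame(y, index=ids, columns=mets)

    # --- technical layer ---------------------------------------------------
    batch_idx = np.arange(nd) // config.batch_size
    n_batches = int(batch_idx.max()) + 1
    run_of_batch = (np.arange(n_batches) * config.n_runs) // n_batches
    run_order = np.arange(nd) % config.batch_size + 1
    drift_int = rng.normal(0.0, config.drift_spec.intercept_sd, (n_batches, m))
    drift_slope = rng.normal(0.0, config.drift_spec.slope_sd, (n_batches, m))
    shift = rng.normal(0.0, config.sample_shift_sd, nd)

    travel = np.clip(np.exp(rng.normal(np.log(26.0), 0.35, nd)), 14.0, 169.0)
    temp = np.clip(rng.normal(18.8, 4.0, nd), 1.8, 28.7)
    hemolysis = rng.choice(len(config.hemolysis_rates), size=nd, p=config.hemolysis_rates)

    log_raw = (
        y
        + drift_int[batch_idx]
        + drift_slope[batch_idx] * run_order[:, None]
        + shift[:, None]
    )
    if config.tech_effect_sd > 0:
        tt_slope = rng.normal(0.0, config.tech_effect_sd, m)
        at_slope = rng.normal(0.0, config.tech_effect_sd, m)
        log_raw = log_raw + np.outer(travel - travel.mean(), tt_slope)
        log_raw = log_raw + np.outer(temp - temp.mean(), at_slope)
    if config.contamination:
        k = min(5, m)
        log_raw[:, :k] += config.contamination_shift * (hemolysis == 4)[:, None]
    raw = np.exp(log_raw)
    if config.missing_rate > 0:
        mask = rng.random((nd, m)) < config.missing_rate
        raw = np.where(mask, np.nan, raw)

    values = pd.DataFrame(raw, index=ids, columns=mets)
    meta = pd.DataFrame(
        {
            "batch": [f"batch_{b:02d}" for b in batch_idx],
            "run": [f"run_{r}" for r in run_of_batch[batch_idx]],
            "run_order": run_order,
            "hemolysis": hemolysis,
            "travel_time": travel,
            "arrival_temp": temp,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    matrix = MetaboliteMatrix(values, meta, state="raw")
    truth = GroundTruth(
        true_beta=true_beta,
        true_h2=h2,
        true_acme=acme,
        true_prop_mediated=prop,
        breeding_values=pd.DataFrame(bv, index=ids, columns=mets),
        latent=latent,
        drift_intercepts=drift_int,
        drift_slopes=drift_slope,
    )
    return matrix, cohort, truth


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[MetaboliteMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Convenience bundle: genotypes -> GRM -> phenotypes.

    Returns (matrix, cohort, genotypes, ancestry, truth).  The GRM used for
    simulation is recomputed by callers that need it (kinship.compute_grm).
    """
    from .kinship import compute_grm, filter_snps

    genotypes, ancestry = simulate_genotypes(config)
    kin = compute_grm(filter_snps(genotypes))
    matrix, cohort, truth = simulate_phenotypes(config, genotypes, kin)
    return matrix, cohort, genotypes, ancestry, truth
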