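"""Synthetic experimental designs, confidence-rating observers and cohorts.

Three layers, each usable on its own:

* **Designs** — the 2-AFC dot-numerosity task (a 272-dot reference box vs a
  comparison box differing by −64..+64 dots in 8-dot steps; 8 trials per
  condition over 2 blocks = 136 trials) and the country-population knowledge
  task (8 log10-population-ratio bins of width 0.225 on each side, 9 trials
  per signed bin over 2 blocks = 144 trials), with the reference/larger side
  counterbalanced within difficulty level.

* **Observers** — an equal-variance SDT generator: trial evidence
  ``x ~ N(±k·|Δ|/2, 1)`` (so d' = k·|Δ| at level Δ), response by comparing
  ``x`` to a criterion, and confidence obtained by cutting a *noisy copy*
  ``x + ε, ε ~ N(0, meta_noise_sd)`` with an equal-width type-2 criteria
  ladder shifted by ``confidence_shift``.  Zero meta-noise and zero shift
  yield a metacognitively ideal observer (m_ratio = 1).

* **Cohorts** — joint questionnaire + behaviour samples with a planted
  3-factor latent symptom structure (AD, CIT, SW), demographic covariates,
  standardized symptom→behaviour effects (defaults: AD raises and CIT lowers
  the measured confidence criterion, +0.33 / −0.17), and optional guaranteed
  violators of each exclusion rule.  A ground-truth table records every
  planted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .instruments import (BIG5_RANGE, BIG5_SUBSCALES, CATCH_ITEM, FACTOR_NAMES,
                          PSYCHIATRIC_INSTRUMENTS, all_item_ids, item_ids)
from .scoring import FactorWeights

__all__ = [
    "DesignSpec",
    "ObserverParams",
    "CohortSpec",
    "Cohort",
    "generate_design",
    "simulate_observer",
    "simulate_cohort",
    "simulate_model_counts",
    "generate_stimulus_spec",
    "synthetic_factor_weights",
]

PERCEPTION_CONDITIONS = tuple(range(-64, 72, 8))          # 17 signed dot differences
KNOWLEDGE_BIN_EDGES = tuple(np.round(np.arange(0.0, 1.801, 0.225), 3))  # 9 edges, 8 bins
REFERENCE_DOTS = 272


@dataclass(frozen=True)
class DesignSpec:
    task: str                      # "perception" | "knowledge"
    conditions: tuple              # signed evidence levels
    trials_per_condition: int
    blocks: int
    reference_magnitude: int = REFERENCE_DOTS
    bin_edges: Optional[tuple] = None

    @property
    def n_trials(self) -> int:
        return len(self.conditions) * self.trials_per_condition


@dataclass
class ObserverParams:
    """Generative observer: type-1 sensitivity/bias and type-2 noise/bias."""

    sensitivity_scale: float       # k: |evidence| -> d'
    criterion: float = 0.0         # c > 0 biases toward "left" responses
    meta_noise_sd: float = 0.0     # extra noise on the confidence copy
    confidence_shift: float = 0.0  # ladder offset; >0 pushes criteria outwards
    K: int = 6
    t2c_first: float = 0.4         # first type-2 criterion offset from c
    t2c_spacing: float = 0.35      # equal ladder spacing
    nonresponse_rate: float = 0.0
    constant_confidence: Optional[int] = None

    def __post_init__(self) -> None:
        if self.meta_noise_sd < 0:
            raise ValueError("meta_noise_sd must be >= 0")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not 0 <= self.nonresponse_rate <= 1:
            raise ValueError("nonresponse_rate must be a probability")


def generate_design(task: str = "perception", trials_per_condition: int | None = None,
                    blocks: int = 2, seed: int = 0,
                    conditions: tuple | None = None) -> tuple[DesignSpec, pd.DataFrame]:
    """Build a design and a pseudo-random ordered trial list.

    The larger-stimulus (reference, for the dot task) side is counterbalanced
    within each difficulty level; the presentation order is shuffled by
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    if task == "perception":
        conds = tuple(conditions) if conditions is not None else PERCEPTION_CONDITIONS
        tpc = 8 if trials_per_condition is None else trials_per_condition
        if tpc % 2:
            raise ValueError("trials_per_condition must be even for strict "
                             "within-condition counterbalancing of the reference side")
        spec = DesignSpec(task, conds, tpc, blocks)
        rows = []
        for delta in conds:
            for j in range(tpc):
                ref_right = j >= tpc // 2
                # evidence = dots(right) - dots(left); comparison = reference + delta
                ev = -delta if ref_right else delta
                stim = "right" if ev > 0 else "left"
                if ev == 0:  # identical condition: label the comparison side
                    stim = "left" if ref_right else "right"
                rows.append((delta, ev, stim, "right" if ref_right else "left"))
        df = pd.DataFrame(rows, columns=["condition", "evidence_level",
                                         "stimulus_side", "reference_side"])
    elif task == "knowledge":
        nbins = len(KNOWLEDGE_BIN_EDGES) - 1
        conds = tuple(conditions) if conditions is not None else \
            tuple(b for b in range(-nbins, nbins + 1) if b != 0)
        tpc = 9 if trials_per_condition is None else trials_per_condition
        spec = DesignSpec(task, conds, tpc, blocks, bin_edges=KNOWLEDGE_BIN_EDGES)
        rows = []
        for b in conds:
            for j in range(tpc):
                stim = "right" if b > 0 else "left"
                rows.append((b, b, stim, f"bin{abs(b)}_pair{j + 1:02d}"))
        df = pd.DataFrame(rows, columns=["condition", "evidence_level",
                                         "stimulus_side", "pair_id"])
    else:
        raise ValueError(f"unknown task {task!r}")

    if len(df) % blocks:
        raise ValueError("total trial count must divide evenly into blocks")
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    per_block = len(df) // blocks
    df.insert(0, "block", np.repeat(np.arange(1, blocks + 1), per_block))
    df.insert(0, "trial", np.arange(1, len(df) + 1))
    return spec, df


def generate_stimulus_spec(spec: DesignSpec, trials: pd.DataFrame, index: int) -> dict:
    """Abstract dot-stimulus description for one perceptual trial (no rendering)."""
    if spec.task != "perception":
        raise ValueError("stimulus specs are defined for the perception task")
    row = trials.iloc[index]
    delta = int(row["condition"])
    if delta not in spec.conditions:
        raise ValueError(f"evidence level {delta} outside the condition set")
    ref_side = row["reference_side"]
    comp_side = "left" if ref_side == "right" else "right"
    return {
        "reference_side": ref_side,
        "reference_count": spec.reference_magnitude,
        "comparison_side": comp_side,
        "comparison_count": spec.reference_magnitude + delta,
    }


def _evidence_strength(task: str, evidence_level: np.ndarray) -> np.ndarray:
    """Signed physical evidence: dot difference, or log-ratio bin midpoint."""
    ev = np.asarray(evidence_level, dtype=float)
    if task == "perception":
        return ev
    width = KNOWLEDGE_BIN_EDGES[1] - KNOWLEDGE_BIN_EDGES[0]
    return np.sign(ev) * (np.abs(ev) - 0.5) * width


def _simulate_many(task: str, trials: pd.DataFrame, k: np.ndarray, c: np.ndarray,
                   meta_noise: np.ndarray, shift: np.ndarray, K: int,
                   t2c_first: float, t2c_spacing: float,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorised observer simulation: n participants x T trials."""
    n = len(k)
    strength = _evidence_strength(task, trials["evidence_level"].to_numpy())
    T = len(strength)
    mu = 0.5 * k[:, None] * strength[None, :]
    x = mu + rng.standard_normal((n, T))
    resp_right = x > c[:, None]
    x2 = x + meta_noise[:, None] * rng.standard_normal((n, T))
    # equal-width ladder, shifted; ordering kept by clipping + running max
    j = np.arange(K - 1)
    offsets = t2c_first + t2c_spacing * j[None, :] + shift[:, None]
    offsets = np.maximum.accumulate(np.clip(offsets, 0.02, None), axis=1)  # (n, K-1)
    upper = c[:, None, None] + offsets[:, None, :]   # (n, 1, K-1) vs x2 (n, T)
    lower = c[:, None, None] - offsets[:, None, :]
    conf_right = 1 + (x2[:, :, None] > upper).sum(axis=2)
    conf_left = 1 + (x2[:, :, None] < lower).sum(axis=2)
    conf = np.where(resp_right, conf_right, conf_left)
    return {"resp_right": resp_right, "confidence": conf}


def _trials_frame(task: str, trials: pd.DataFrame, participant_id: str,
                  sim: dict, row: int, responded: np.ndarray,
                  constant_confidence: Optional[int]) -> pd.DataFrame:
    T = len(trials)
    resp = np.where(sim["resp_right"][row], "right", "left").astype(object)
    conf = sim["confidence"][row].astype(float)
    if constant_confidence is not None:
        conf[:] = constant_confidence
    resp[~responded] = None
    conf[~responded] = np.nan
    return pd.DataFrame({
        "participant_id": participant_id,
        "task": task,
        "block": trials["block"].to_numpy(),
        "trial": trials["trial"].to_numpy(),
        "evidence_level": trials["evidence_level"].to_numpy(),
        "stimulus_side": trials["stimulus_side"].to_numpy(),
        "response_side": resp,
        "confidence": conf,
        "responded": responded,
    })


def simulate_observer(trials: pd.DataFrame, params: ObserverParams, seed: int = 0,
                      participant_id: str = "sim", task: str = "perception") -> pd.DataFrame:
    """Simulate one observer through an ordered trial list (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    sim = _simulate_many(task, trials,
                         np.array([params.sensitivity_scale]),
                         np.array([params.criterion]),
                         np.array([params.meta_noise_sd]),
                         np.array([params.confidence_shift]),
                         params.K, params.t2c_first, params.t2c_spacing, rng)
    T = len(trials)
    responded = np.ones(T, dtype=bool)
    if params.nonresponse_rate > 0:
        responded = rng.random(T) >= params.nonresponse_rate
    return _trials_frame(task, trials, participant_id, sim, 0, responded,
                         params.constant_confidence)


def simulate_model_counts(n_trials: int, d_prime: float, m_ratio: float,
                          c: float = 0.0, t2c_offsets: np.ndarray | None = None,
                          K: int = 6, seed: int = 0) -> "RatingCounts":
    """Draw a rating-count table from the meta-d' model itself.

    Type-1 responses follow equal-variance SDT with (``d_prime``, ``c``);
    confidence is multinomial with the conditional band probabilities of a
    meta-level observer at ``meta_d = m_ratio * d_prime`` whose type-2
    criteria sit at ``meta_c ± t2c_offsets``.  Useful for parameter-recovery
    tests where the generative Mratio must be exact.
    """
    from scipy.stats import norm as _norm

    from .metad import _band_probs
    from .sdt import RatingCounts

    rng = np.random.default_rng(seed)
    if t2c_offsets is None:
        t2c_offsets = 0.4 + 0.35 * np.arange(K - 1)
    t2c_offsets = np.asarray(t2c_offsets, dtype=float)
    meta_d = m_ratio * d_prime
    c_rel = c / d_prime
    meta_c = c_rel * meta_d
    p_right = np.array([1 - _norm.cdf(c + d_prime / 2),   # stim left
                        1 - _norm.cdf(c - d_prime / 2)])  # stim right
    bands = _band_probs(meta_d, meta_c, meta_c - t2c_offsets, meta_c + t2c_offsets, K)
    counts = np.zeros((2, 2, K))
    n_per_stim = (n_trials // 2, n_trials - n_trials // 2)
    for s in (0, 1):
        n_right = rng.binomial(n_per_stim[s], p_right[s])
        for r, nr in ((1, n_right), (0, n_per_stim[s] - n_right)):
            counts[s, r] = rng.multinomial(nr, bands[s, r])
    return RatingCounts(counts, K)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: calibration of the planted confidence-criterion effect (see docs/methods.md):
#: measured criterion ~= CRIT_SLOPE * confidence_shift + noise(var CRIT_MEAS_VAR)
#: at the default perception design; EFFECT_SCALE is the total latent SD of the
#: measured criterion's planted component, in criterion units.
CRIT_SLOPE = 0.855
CRIT_MEAS_VAR = 0.0108
EFFECT_SCALE = 0.25

DEFAULT_FACTOR_COV = np.array([[1.0, 0.4, 0.4],
                               [0.4, 1.0, 0.4],
                               [0.4, 0.4, 1.0]])

DEFAULT_EFFECT_MAP: dict[str, dict[str, float]] = {
    # standardized effects on the *measured* per-participant outcome
    "confidence_criterion": {"AD": 0.33, "CIT": -0.17},
}

DEFAULT_BIG5_COUPLING: dict[str, dict[str, float]] = {
    "neuroticism": {"AD": 0.5},
    "extraversion": {"SW": -0.3},
}

BASE_SENSITIVITY = {"perception": 0.045, "knowledge": 1.6}


@dataclass
class CohortSpec:
    n: int = 500
    seed: int = 0
    tasks: tuple = ("perception",)
    factor_cov: np.ndarray = field(default_factory=lambda: DEFAULT_FACTOR_COV.copy())
    effect_map: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                      DEFAULT_EFFECT_MAP.items()})
    item_noise_sd: float = 1.0
    loading_matrix: Optional[FactorWeights] = None
    violators: dict = field(default_factory=dict)
    big5_coupling: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                         DEFAULT_BIG5_COUPLING.items()})
    base_sensitivity: dict = field(default_factory=lambda: dict(BASE_SENSITIVITY))
    base_meta_noise: float = 0.25
    base_criterion: float = 0.05
    sensitivity_cv: float = 0.15   # lognormal SD of per-subject sensitivity
    criterion_sd: float = 0.10
    meta_noise_sd_between: float = 0.10
    include_big5: bool = True
    # ladder start sits clear of the criterion so planted negative shifts
    # rarely hit the ordering floor (keeps the shift->criterion map linear)
    t2c_first: float = 0.55
    t2c_spacing: float = 0.35

    def __post_init__(self) -> None:
        cov = np.asarray(self.factor_cov, dtype=float)
        if cov.shape != (3, 3) or np.any(np.linalg.eigvalsh(cov) <= 0):
            raise ValueError("factor_cov must be a 3x3 positive-definite matrix")
        self.factor_cov = cov


@dataclass
class Cohort:
    demographics: pd.DataFrame       # participant_id, age, gender
    trials: dict                     # task -> long trial table
    items: pd.DataFrame              # n x 209 analysis items (LSAS collapsed)
    big5_items: Optional[pd.DataFrame]
    lsas_fear: pd.DataFrame          # n x 24 raw fear/anxiety answers
    lsas_avoidance: pd.DataFrame
    catch: pd.DataFrame              # participant_id, response
    ground_truth: pd.DataFrame
    weights: FactorWeights

    def questionnaire_long(self) -> pd.DataFrame:
        """Long-format item responses (participant_id, instrument, item_id, response)."""
        frames = []
        for name in PSYCHIATRIC_INSTRUMENTS:
            ids = item_ids(name)
            sub = self.items[ids].copy()
            sub["participant_id"] = self.items.index
            long = sub.melt(id_vars="participant_id", var_name="item_id",
                            value_name="response")
            long.insert(1, "instrument", name)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)


def synthetic_factor_weights(seed: int = 0) -> FactorWeights:
    """Synthetic stand-in for the published 209 x 3 transdiagnostic weights.

    Items load dominantly on their instrument's factor with small
    cross-loadings; reverse-keyed items carry negated weights because the
    stored responses are administered-coded.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for name, cfg in PSYCHIATRIC_INSTRUMENTS.items():
        dom = cfg["factor"]
        for i, item in enumerate(item_ids(name), start=1):
            w = {f: rng.normal(0.0, 0.08) for f in FACTOR_NAMES}
            w[dom] = rng.uniform(0.45, 0.85)
            if i in cfg["reverse"]:
                w = {f: -v for f, v in w.items()}
            rows.append({"item_id": item, **w})
    df = pd.DataFrame(rows).set_index("item_id")[list(FACTOR_NAMES)]
    return FactorWeights(df)


def _ordinal_map(latent: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Linear rescale of an ~N(0,1)-scale latent onto an ordinal response range."""
    v = np.clip(latent, -3.0, 3.0)
    return np.clip(np.round(lo + (hi - lo) * (v + 3.0) / 6.0), lo, hi)


def _assign_violators(violators: dict, n: int) -> dict[str, np.ndarray]:
    """Resolve rule -> participant indices; integer counts get distinct ids."""
    out: dict[str, np.ndarray] = {}
    cursor = 0
    for rule in sorted(violators):
        v = violators[rule]
        if isinstance(v, (int, np.integer)):
            if cursor + v > n:
                raise ValueError("more planted violators than participants")
            out[rule] = np.arange(cursor, cursor + v)
            cursor += v
        else:
            out[rule] = np.asarray(v, dtype=int)
    return out


def _plant_structured_effect(targets: dict[str, float], z_sources: dict[str, np.ndarray],
                             factor_cov: np.ndarray, rng: np.random.Generator,
                             scale: float, slope: float, meas_var: float) -> np.ndarray:
    """Latent shift carrying prescribed standardized effects on a measured outcome.

    The structural part ``sum_k beta_k z_k`` is completed with noise that is
    orthogonalised against the sources, so the planted coefficients hold
    exactly in-sample (not just in expectation); after the measurement step
    (linear slope + measurement variance, both calibrated constants) the
    standardized regression of the measured outcome on the sources recovers
    the planted betas up to measurement noise alone.
    """
    n = len(next(iter(z_sources.values())))
    struct = np.zeros(n)
    order = list(z_sources)
    beta = np.array([targets.get(s, 0.0) for s in order])
    for b, s in zip(beta, order):
        struct += b * z_sources[s]
    var_struct = float(np.var(struct))  # empirical: sources may be correlated
    var_resid = 1.0 - var_struct - meas_var / scale ** 2
    if var_resid < 0:
        raise ValueError("planted effects too large for the chosen effect scale")
    eps = rng.standard_normal(n)
    Z = np.column_stack([np.ones(n)] + [z_sources[s] for s in order])
    eps -= Z @ np.linalg.lstsq(Z, eps, rcond=None)[0]   # project out the sources
    sd = eps.std()
    if sd > 0:
        eps *= np.sqrt(var_resid) / sd
    eta = struct + eps
    return (scale / slope) * eta


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic cohort: demographics, questionnaires, behaviour.

    Deterministic given ``spec.seed``; every planted parameter is recorded in
    the ground-truth table.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    pid = np.array([f"p{i:04d}" for i in range(n)], dtype=object)

    # --- demographics ------------------------------------------------------
    age = np.clip(np.round(rng.normal(25, 9, n)), 18, 70).astype(int)
    gender = np.where(rng.random(n) < 0.5, "female", "male").astype(object)

    # --- latent symptom factors and questionnaire items --------------------
    L = np.linalg.cholesky(spec.factor_cov)
    factors = rng.standard_normal((n, 3)) @ L.T          # AD, CIT, SW (z-scale)
    weights = spec.loading_matrix or synthetic_factor_weights(spec.seed)
    W = weights.weights.to_numpy(dtype=float)            # administered-coded
    latent_items = factors @ W.T + spec.item_noise_sd * rng.standard_normal((n, 209))

    ids = all_item_ids()
    items = pd.DataFrame(index=pd.Index(pid, name="participant_id"),
                         columns=ids, dtype=float)
    col = 0
    lsas_fear = lsas_avoid = None
    for name, cfg in PSYCHIATRIC_INSTRUMENTS.items():
        m = cfg["n_items"]
        block = latent_items[:, col:col + m]
        if name == "lsas":
            fear = _ordinal_map(block + 0.4 * rng.standard_normal((n, m)),
                                cfg["min"], cfg["max"])
            avoid = _ordinal_map(block + 0.4 * rng.standard_normal((n, m)),
                                 cfg["min"], cfg["max"])
            lsas_fear = pd.DataFrame(fear, index=items.index, columns=item_ids(name))
            lsas_avoid = pd.DataFrame(avoid, index=items.index, columns=item_ids(name))
            vals = (fear + avoid) / 2.0
        else:
            vals = _ordinal_map(block, cfg["min"], cfg["max"])
        items.iloc[:, col:col + m] = vals
        col += m

    # --- Big-5 -------------------------------------------------------------
    big5_items = None
    big5_latents = {}
    if spec.include_big5:
        lo, hi = BIG5_RANGE
        cols, data = [], []
        start = 1
        for sub, m in BIG5_SUBSCALES.items():
            coupling = spec.big5_coupling.get(sub, {})
            struct = sum(r * factors[:, FACTOR_NAMES.index(f)]
                         for f, r in coupling.items())
            var_s = sum(r ** 2 for r in coupling.values())  # factors ~unit variance
            lat = struct + np.sqrt(max(1 - var_s, 1e-9)) * rng.standard_normal(n)
            big5_latents[sub] = lat
            block = 0.6 * lat[:, None] + 0.8 * rng.standard_normal((n, m))
            data.append(_ordinal_map(block, lo, hi))
            cols.extend(f"bfi_{i:02d}" for i in range(start, start + m))
            start += m
        big5_items = pd.DataFrame(np.hstack(data), index=items.index, columns=cols)

    # --- observer parameters with planted effects --------------------------
    # Effects are planted on the *scored* symptom dimensions (what the
    # analysis regresses on), so recovery is not attenuated by item noise;
    # tiny cohorts where scoring is ill-posed fall back to the latents.
    try:
        from .scoring import score_factors
        scored = score_factors(items, weights).to_numpy()
    except ValueError:
        scored = (factors - factors.mean(0)) / factors.std(0)
    z_sources = {
        "AD": scored[:, 0], "CIT": scored[:, 1], "SW": scored[:, 2],
        "age": (age - age.mean()) / max(age.std(), 1e-9),
        "gender": ((gender == "male").astype(float) - (gender == "male").mean())
                  / max((gender == "male").astype(float).std(), 1e-9),
    }
    shift = np.zeros(n)
    eta_map = spec.effect_map.get("confidence_criterion")
    if eta_map:
        shift = _plant_structured_effect(eta_map, z_sources, spec.factor_cov, rng,
                                         EFFECT_SCALE, CRIT_SLOPE, CRIT_MEAS_VAR)

    sens = {t: spec.base_sensitivity[t]
            * np.exp(rng.normal(0.0, spec.sensitivity_cv, n)) for t in spec.tasks}
    crit = rng.normal(spec.base_criterion, spec.criterion_sd, n)
    meta_noise = np.abs(rng.normal(spec.base_meta_noise, spec.meta_noise_sd_between, n))
    for target, betas in spec.effect_map.items():
        if target == "confidence_criterion":
            continue
        delta = sum(b * z_sources[s] for s, b in betas.items())
        if target == "sensitivity_scale":
            for t in spec.tasks:
                sens[t] = sens[t] * np.exp(delta)
        elif target == "criterion":
            crit = crit + delta
        elif target == "meta_noise_sd":
            meta_noise = np.abs(meta_noise + delta)
        elif target == "confidence_shift":
            shift = shift + delta
        else:
            raise ValueError(f"unknown effect target {target!r}")

    # --- planted violators -------------------------------------------------
    vio = _assign_violators(spec.violators, n)
    flags = {rule: np.zeros(n, dtype=bool) for rule in
             ("under_18", "missing_gender", "chance_performer", "constant_confidence",
              "catch_fail", "knowledge_nonresponse")}
    for rule, idx in vio.items():
        if rule not in flags:
            raise ValueError(f"unknown violator rule {rule!r}")
        flags[rule][idx] = True
    age[flags["under_18"]] = rng.integers(16, 18, flags["under_18"].sum())
    gender[flags["missing_gender"]] = None
    for t in spec.tasks:
        sens[t][flags["chance_performer"]] = 0.0

    # --- behaviour ---------------------------------------------------------
    trials_out: dict[str, pd.DataFrame] = {}
    catch_resp = np.full(n, CATCH_ITEM["required_response"], dtype=object)
    catch_resp[flags["catch_fail"]] = "Some of the time"
    for t in spec.tasks:
        dspec, base_trials = generate_design(t, seed=spec.seed)
        T = len(base_trials)
        order = rng.permuted(np.tile(np.arange(T), (n, 1)), axis=1)
        sim = _simulate_many(t, base_trials, sens[t], crit, meta_noise, shift,
                             6, spec.t2c_first, spec.t2c_spacing, rng)
        # presentation order is per-participant; gather trial and response
        # arrays into one long table without a per-participant loop
        ev = base_trials["evidence_level"].to_numpy()[order]
        stim = base_trials["stimulus_side"].to_numpy(dtype=object)[order]
        resp = np.where(np.take_along_axis(sim["resp_right"], order, axis=1),
                        "right", "left").astype(object)
        conf = np.take_along_axis(sim["confidence"], order, axis=1).astype(float)
        conf[flags["constant_confidence"], :] = 4.0
        responded = np.ones((n, T), dtype=bool)
        if t == "knowledge":
            for i in np.flatnonzero(flags["knowledge_nonresponse"]):
                responded[i, rng.choice(T, 6, replace=False)] = False
        resp[~responded] = None
        conf[~responded] = np.nan
        frame = pd.DataFrame({
            "participant_id": np.repeat(pid, T),
            "task": t,
            "block": np.tile(np.repeat(np.arange(1, dspec.blocks + 1),
                                       T // dspec.blocks), n),
            "trial": np.tile(np.arange(1, T + 1), n),
            "evidence_level": ev.reshape(-1),
            "stimulus_side": stim.reshape(-1),
            "response_side": resp.reshape(-1),
            "confidence": conf.reshape(-1),
            "responded": responded.reshape(-1),
        })
        for i in np.flatnonzero(flags["chance_performer"]):
            block = frame.iloc[i * T:(i + 1) * T]
            fixed = block.copy()
            _force_below_chance(fixed, rng)
            frame.iloc[i * T:(i + 1) * T] = fixed
        trials_out[t] = frame

    demographics = pd.DataFrame({"participant_id": pid, "age": age, "gender": gender})
    gt = pd.DataFrame({
        "participant_id": pid,
        "AD": factors[:, 0], "CIT": factors[:, 1], "SW": factors[:, 2],
        "age": age, "gender": gender,
        "criterion": crit, "meta_noise_sd": meta_noise, "confidence_shift": shift,
        **{f"sensitivity_{t}": sens[t] for t in spec.tasks},
        **{f"big5_{s}": v for s, v in big5_latents.items()},
        **{f"violates_{r}": f for r, f in flags.items()},
    })
    return Cohort(demographics=demographics, trials=trials_out, items=items,
                  big5_items=big5_items, lsas_fear=lsas_fear, lsas_avoidance=lsas_avoid,
                  catch=pd.DataFrame({"participant_id": pid, "response": catch_resp}),
                  ground_truth=gt, weights=weights)


def _force_below_chance(frame: pd.DataFrame, rng: np.random.Generator) -> None:
    """Guarantee a planted chance performer violates the accuracy rule.

    Responses on correct non-zero-evidence trials are flipped until accuracy
    (computed as the exclusion rule computes it) falls below 0.5, emulating a
    participant who effectively answered at random or with swapped keys.
    """
    ev = frame["evidence_level"].to_numpy(dtype=float)
    resp = frame["responded"].to_numpy(dtype=bool)
    scored = resp & (ev != 0)
    correct = (frame["stimulus_side"] == frame["response_side"]).to_numpy() & scored
    n_scored = scored.sum()
    target = int(np.floor(0.48 * n_scored))
    excess = int(correct.sum()) - target
    if excess <= 0:
        return
    idx = np.flatnonzero(correct)
    flip = rng.choice(idx, excess, replace=False)
    col = frame.columns.get_loc("response_side")
    frame.iloc[flip, col] = frame.iloc[flip, col].map(
        {"left": "right", "right": "left"})
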