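"""Staged identification of kinetic parameters from assay observables.

A class I scheme carries 48 rate constants, but the three assays probe
nested subsections of the mechanism, so fitting proceeds in three stages
that progressively freeze parameters:

1. *single turnover* -- only the adenylate -> product subscheme is
   exercised; the transfer rate is the identifiable parameter and is set
   so the simulated exponential rate matches the k_tran target.
2. *pyrophosphate exchange* -- the tRNA-free subscheme (12 parameters, of
   which the substrate dissociation constants, the activation rates and
   the PPi release rate dominate kcat/Km); fit to the exchange kcat and
   the ATP / amino-acid Km values.
3. *aminoacylation* -- the full cycle; the remaining tRNA-branch binding
   constants, the activation-with-tRNA rates and the product-release
   rates are tuned to the aminoacylation kcat/Km targets, and the burst
   phenotype is verified.

Parameters identified at an earlier stage are never revisited by a later
one.  Parameters that barely move the targeted observables are filled
from experimental dissociation constants where supplied (``Constraint``)
and from package defaults otherwise (k_on = 1 uM^-1 s^-1 convention for
amino acid, slower for ATP, faster for tRNA).  Adenylate-formation rates
with and without tRNA are tied for class I enzymes; class II (flip-flop)
enzymes untie them, which is what lets a fast exchange kcat coexist with
a slow, burst-free aminoacylation cycle.

All stage observables are evaluated with the deterministic stationary
solver / ODE pipeline, so a fit is a pure function of its inputs and
seed.  Update rules are damped multiplicative corrections (each target is
monotone in its designated knob) followed by a seeded log-normal random
refinement when the loop alone does not reach tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import schemes as sch
from .assays import AssayError, run_burst_assay, run_km_assay, run_single_turnover
from .estimators import EstimatorError
from .schemes import EnzymeModel, RateSet, ReactionScheme

__all__ = ["FitTargets", "Constraint", "FitReport", "FittingError",
           "default_rateset", "apply_constraints", "predict_observables",
           "fit_stage_single_turnover", "fit_stage_pp_exchange",
           "fit_stage_aminoacylation", "fit_enzyme"]


class FittingError(RuntimeError):
    pass


@dataclass
class FitTargets:
    """Target observables (s^-1 / uM) with a relative tolerance."""

    pp_kcat: float | None = None
    pp_km_aa: float | None = None
    pp_km_atp: float | None = None
    aa_kcat: float | None = None
    aa_km_aa: float | None = None
    aa_km_trna: float | None = None
    aa_km_atp: float | None = None
    k_tran: float | None = None
    k_chem: float | None = None
    burst: bool | None = None      # None = ignore
    tolerance: float = 0.15

    def __post_init__(self):
        if not (0.0 < self.tolerance <= 1.0):
            raise ValueError("tolerance must be in (0, 1]")
        for name in ("pp_kcat", "pp_km_aa", "pp_km_atp", "aa_kcat",
                     "aa_km_aa", "aa_km_trna", "aa_km_atp", "k_tran", "k_chem"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"target {name} must be positive")

    def numeric(self) -> dict:
        keys = ("pp_kcat", "pp_km_aa", "pp_km_atp", "aa_kcat", "aa_km_aa",
                "aa_km_trna", "aa_km_atp", "k_tran", "k_chem")
        return {k: getattr(self, k) for k in keys if getattr(self, k) is not None}


@dataclass(frozen=True)
class Constraint:
    """Pin a step's K_d, k_on or k_off to an experimental value."""

    step_id: str
    kind: str                  # "K_d" | "k_on" | "k_off"
    value: float
    note: str = ""

    def __post_init__(self):
        if self.kind not in ("K_d", "k_on", "k_off"):
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        if self.value <= 0:
            raise ValueError("constraint values must be positive")


@dataclass
class FitReport:
    seed: int
    success: bool = True
    messages: list = field(default_factory=list)
    loss_trace: list = field(default_factory=list)
    fixed: set = field(default_factory=set)   # "step:kf"-style fixed dims

    def log(self, msg: str):
        self.messages.append(msg)

    def fail(self, msg: str):
        self.success = False
        self.messages.append("FAIL: " + msg)


# ---------------------------------------------------------------------------
# defaults and constraints
# ---------------------------------------------------------------------------

#: default (k_f, k_b) per step id; binding forward rates in uM^-1 s^-1
_DEFAULTS = {
    # amino acid binding: k_on 5 uM^-1 s^-1, K_d 100 uM (rapid equilibrium)
    "aa_bind": (5.0, 500.0), "aa_bind_t": (5.0, 500.0),
    "aa_bind_r": (5.0, 500.0), "aa_bind_rt": (5.0, 500.0),
    "aa_bind_2": (5.0, 500.0), "aa_bind_2t": (5.0, 500.0),
    # ATP binding: k_on 0.1 uM^-1 s^-1, K_d 1000 uM (faster on the tRNA
    # branch, where capture time feeds straight into k_chem)
    "atp_bind": (0.1, 100.0), "atp_bind_a": (0.1, 100.0),
    "atp_bind_r": (0.2, 200.0), "atp_bind_ra": (0.2, 200.0),
    "atp_bind_2": (0.1, 100.0), "atp_bind_2a": (0.1, 100.0),
    "atp_bind_p": (0.1, 100.0),
    # tRNA binding: slow dissociation (committed capture); the adenylate
    # state is the high-affinity entry point, so substrate-free states get
    # a weaker on-rate
    "trna_bind_0": (1.0, 0.5), "trna_bind_a": (1.0, 0.5),
    "trna_bind_t": (1.0, 0.5), "trna_bind_at": (1.0, 0.5),
    "trna_bind_d": (3.0, 0.5),
    # catalysis
    "act": (400.0, 200.0), "act_r": (400.0, 200.0), "act_2": (400.0, 200.0),
    "tran": (15.0, 0.5), "tran_p": (15.0, 0.5),
    # dissociations (backward = rebinding, uM^-1 s^-1)
    # PPi release after activation-with-tRNA is fast (it is not a
    # kcat/Km-sensitive dimension and should not delay transfer)
    "ppi_rel": (300.0, 0.15), "ppi_rel_r": (1000.0, 0.15),
    "ppi_rel_q": (1000.0, 0.15), "ppi_rel_2": (1000.0, 0.15),
    "amp_rel": (300.0, 0.05),
    "prod_rel": (5.0, 0.01), "prod_rel_t": (5.0, 0.01),
    "prod_rel_dp": (50.0, 0.01), "prod_rel_d": (50.0, 0.01),
}


def default_rateset(scheme: ReactionScheme) -> RateSet:
    """Package default rates for every step of ``scheme``."""
    missing = [st.id for st in scheme.steps if st.id not in _DEFAULTS]
    if missing:
        raise FittingError(f"no default rates for steps {missing}")
    return RateSet({st.id: _DEFAULTS[st.id] for st in scheme.steps})


def apply_constraints(rates: RateSet, constraints) -> tuple:
    """Apply constraints; returns (rates, frozen-dimension set).

    A ``K_d`` constraint fixes the ratio k_b/k_f (adjusting k_b); ``k_on``
    and ``k_off`` pin the individual rate constants bitwise.
    """
    frozen = set()
    updates = {}
    by_step: dict = {}
    for c in constraints or ():
        by_step.setdefault(c.step_id, []).append(c)
    for sid, cs in by_step.items():
        kinds = [c.kind for c in cs]
        if kinds.count("K_d") > 1 or kinds.count("k_on") > 1 or kinds.count("k_off") > 1:
            raise FittingError(f"conflicting constraints on step {sid}")
        kf, kb = rates[sid]
        for c in cs:
            if c.kind == "k_on":
                kf = c.value
                frozen.add(f"{sid}:kf")
            elif c.kind == "k_off":
                kb = c.value
                frozen.add(f"{sid}:kb")
        for c in cs:
            if c.kind == "K_d":
                kb = c.value * kf
                frozen.add(f"{sid}:kd")
        updates[sid] = (kf, kb)
    return rates.replace(**updates), frozen


# ---------------------------------------------------------------------------
# deterministic observable pipeline
# ---------------------------------------------------------------------------

def predict_observables(model: EnzymeModel, which=None,
                        include_chem: bool = False) -> dict:
    """Deterministic (stationary-solver / ODE) observables of a model.

    Keys: pp_kcat, pp_km_aa, pp_km_atp, aa_kcat, aa_km_aa, aa_km_trna,
    k_tran, burst (and k_chem on request).  Unavailable observables are
    omitted rather than raising.
    """
    want = set(which) if which is not None else {
        "pp", "aa", "k_tran", "burst"} | ({"k_chem"} if include_chem else set())
    out: dict = {}
    if "pp" in want and not model.trna_required:
        try:
            _, fit_aa = run_km_assay(model, "pp_exchange", "AA", method="ode")
            _, fit_atp = run_km_assay(model, "pp_exchange", "ATP", method="ode")
            if fit_aa.valid:
                out["pp_kcat"] = fit_aa.kcat
                out["pp_km_aa"] = fit_aa.km
            if fit_atp.valid:
                out["pp_km_atp"] = fit_atp.km
        except (AssayError, EstimatorError):
            pass
    if "aa" in want:
        try:
            _, fit_t = run_km_assay(model, "aminoacylation", "tRNA", method="ode")
            _, fit_a = run_km_assay(model, "aminoacylation", "AA", method="ode")
            if fit_t.valid:
                out["aa_kcat"] = fit_t.kcat
                out["aa_km_trna"] = fit_t.km
            if fit_a.valid:
                out["aa_km_aa"] = fit_a.km
        except (AssayError, EstimatorError):
            pass
    if "k_tran" in want:
        try:
            out["k_tran"] = run_single_turnover(model, "transfer", method="ode").rate
        except (AssayError, EstimatorError):
            pass
    if "k_chem" in want:
        try:
            out["k_chem"] = run_single_turnover(model, "chem", method="ode").rate
        except (AssayError, EstimatorError):
            pass
    if "burst" in want:
        try:
            out["burst"] = run_burst_assay(model, method="ode").burst
        except (AssayError, EstimatorError):
            pass
    return out


def _loss(pred: dict, targets: dict, weights: dict | None = None) -> float:
    tot = 0.0
    for k, tv in targets.items():
        w = (weights or {}).get(k, 1.0)
        pv = pred.get(k)
        if pv is None or pv <= 0:
            tot += 25.0 * w
        else:
            tot += w * math.log(pv / tv) ** 2
    return tot


def _within(pred: dict, targets: dict, tol: float) -> bool:
    for k, tv in targets.items():
        pv = pred.get(k)
        if pv is None or abs(pv - tv) > tol * tv:
            return False
    return True


def _scale(rates: RateSet, frozen, sid: str, f_kf=1.0, f_kb=1.0) -> RateSet:
    """Multiply a step's rates, honouring frozen dims (K_d preserved)."""
    kf, kb = rates[sid]
    if f"{sid}:kf" not in frozen:
        kf *= f_kf
    if f"{sid}:kb" not in frozen:
        kb *= f_kb
    if f"{sid}:kd" in frozen:
        kd = rates.kb(sid) / rates.kf(sid) if rates.kf(sid) > 0 else 0.0
        kb = kd * kf
    return rates.replace(**{sid: (kf, kb)})


def _clip(x, lo=0.25, hi=4.0):
    return min(max(x, lo), hi)


# ---------------------------------------------------------------------------
# stage 1: single turnover
# ---------------------------------------------------------------------------

_ST_STEPS = ("trna_bind_d", "tran", "amp_rel", "prod_rel")


def fit_stage_single_turnover(scheme: ReactionScheme, targets: FitTargets,
                              constraints=(), seed: int = 0,
                              rates: RateSet | None = None):
    """Set the single-turnover subscheme so k_tran matches its target.

    Returns ``(rates, fixed_dims, report)``.  The transfer rate is the
    identifiable knob (AMP/product release are downstream of the counted
    transfer event); it and any constrained parameters are frozen for the
    later stages.
    """
    if targets.k_tran is None or targets.k_tran <= 0:
        raise FittingError("stage 1 requires a positive k_tran target")
    if rates is None:
        rates = default_rateset(scheme)
    rates, frozen = apply_constraints(rates, constraints)
    report = FitReport(seed=seed)

    present = {st.id for st in scheme.steps}
    tie_tran = "tran_p" in present

    def pred(r):
        model_like = (scheme, r)
        return run_single_turnover(model_like, "transfer", method="ode").rate

    target = targets.k_tran
    for _ in range(12):
        p = pred(rates)
        report.loss_trace.append(_loss({"k_tran": p}, {"k_tran": target}))
        if abs(p - target) <= 0.02 * target:
            break
        f = _clip(target / p)
        rates = _scale(rates, frozen, "tran", f_kf=f)
        if tie_tran and "tran_p:kf" not in frozen:
            rates = rates.replace(tran_p=(rates.kf("tran"), rates.kb("tran_p")))
    p = pred(rates)
    if abs(p - target) > targets.tolerance * target:
        report.fail(f"k_tran {p:.3g} outside tolerance of {target:.3g}")
    # Only the transfer rate is identifiable here: binding is pseudo-first-
    # order and fast at 50 uM enzyme, and AMP/product release sit
    # downstream of the counted transfer event.
    fixed = set(frozen)
    fixed.update({"tran:kf", "tran:kb"})
    if tie_tran:
        fixed.update({"tran_p:kf", "tran_p:kb"})
    report.fixed = fixed
    report.log(f"stage1: k_tran fitted to {p:.4g} (target {target:.4g})")
    return rates, fixed, report


# ---------------------------------------------------------------------------
# stage 2: pyrophosphate exchange
# ---------------------------------------------------------------------------

_PP_STEPS = ("aa_bind", "atp_bind", "aa_bind_t", "atp_bind_a", "act", "ppi_rel")


def fit_stage_pp_exchange(scheme: ReactionScheme, targets: FitTargets,
                          constraints=(), rates: RateSet | None = None,
                          fixed=None, seed: int = 0):
    """Fit the 12 exchange-subscheme parameters to pp kcat / Km targets.

    The sensitive dimensions are the amino-acid and ATP dissociation
    constants, the activation rate pair and the PPi release rate; the
    others stay at constrained/default values.  Returns
    ``(rates, fixed_dims, report)``.
    """
    if targets.pp_kcat is None or (targets.pp_km_aa is None and
                                   targets.pp_km_atp is None):
        raise FittingError("stage 2 requires pp_kcat and at least one pp Km")
    if rates is None:
        rates = default_rateset(scheme)
    crates, frozen = apply_constraints(rates, constraints)
    rates = crates
    frozen = set(frozen) | set(fixed or ())
    report = FitReport(seed=seed)
    tgt = {k: v for k, v in targets.numeric().items() if k.startswith("pp_")}

    def pred(r):
        return predict_observables(_SchemeModel(scheme, r), which={"pp"})

    best = None
    for it in range(15):
        p = pred(rates)
        loss = _loss(p, tgt)
        report.loss_trace.append(loss)
        if best is None or loss < best[0]:
            best = (loss, rates)
        if _within(p, tgt, 0.02):
            break
        new = rates
        if "pp_kcat" in tgt and p.get("pp_kcat"):
            f = _clip(tgt["pp_kcat"] / p["pp_kcat"])
            new = _scale(new, frozen, "act", f_kf=f, f_kb=f)
        if "pp_km_aa" in tgt and p.get("pp_km_aa"):
            f = _clip(tgt["pp_km_aa"] / p["pp_km_aa"])
            for sid in ("aa_bind", "aa_bind_t"):
                new = _scale(new, frozen, sid, f_kb=f)
        if "pp_km_atp" in tgt and p.get("pp_km_atp"):
            f = _clip(tgt["pp_km_atp"] / p["pp_km_atp"])
            for sid in ("atp_bind", "atp_bind_a"):
                new = _scale(new, frozen, sid, f_kb=f)
        rates = new

    p = pred(rates)
    if not _within(p, tgt, targets.tolerance):
        rates = _random_refine(rates, frozen, lambda r: _loss(pred(r), tgt),
                               report, seed,
                               knobs=[("act", "both"), ("ppi_rel", "kf"),
                                      ("aa_bind", "kb"), ("aa_bind_t", "kb"),
                                      ("atp_bind", "kb"), ("atp_bind_a", "kb")])
        p = pred(rates)
    if not _within(p, tgt, targets.tolerance):
        report.fail(f"pp observables {p} outside tolerance of {tgt}")
    fixed_out = set(frozen)
    for sid in _PP_STEPS:
        if sid in {s.id for s in scheme.steps}:
            fixed_out.update({f"{sid}:kf", f"{sid}:kb"})
    report.fixed = fixed_out
    report.log(f"stage2: pp observables {p}")
    return rates, fixed_out, report


class _SchemeModel:
    """Duck-typed stand-in for EnzymeModel inside the fitting loops."""

    def __init__(self, scheme, rates, sites=1, trna_required=False):
        self.scheme = scheme
        self.rates = rates
        self.sites = sites
        self.trna_required = trna_required
        self.name = "probe"


def _random_refine(rates, frozen, loss_fn, report, seed, knobs,
                   budget: int = 60, sigma: float = 0.2):
    """Seeded log-normal jitter around the best point found so far."""
    rng = np.random.default_rng(seed + 17)
    best_rates = rates
    best_loss = loss_fn(rates)
    for _ in range(budget):
        cand = best_rates
        for sid, which in knobs:
            if sid not in cand:
                continue
            f = float(np.exp(rng.normal(0.0, sigma)))
            if which == "both":
                cand = _scale(cand, frozen, sid, f_kf=f, f_kb=f)
            elif which == "kf":
                cand = _scale(cand, frozen, sid, f_kf=f)
            else:
                cand = _scale(cand, frozen, sid, f_kb=f)
        loss = loss_fn(cand)
        if loss < best_loss:
            best_loss, best_rates = loss, cand
    report.loss_trace.append(best_loss)
    return best_rates


# ---------------------------------------------------------------------------
# stage 3: aminoacylation
# ---------------------------------------------------------------------------

def fit_stage_aminoacylation(scheme: ReactionScheme, targets: FitTargets,
                             constraints=(), rates: RateSet | None = None,
                             fixed=None, seed: int = 0,
                             tie_activation: bool = True, sites: int = 1,
                             trna_required: bool = False):
    """Complete the rate set against the aminoacylation observables.

    Free dimensions: the tRNA-branch binding constants (tRNA k_on/k_off,
    amino-acid and ATP K_d with tRNA bound), the with-tRNA activation
    rates (tied to the tRNA-free ones for class I), and the
    product-release rates, which set the aminoacylation kcat for class I
    enzymes.  For flip-flop schemes the with-tRNA activation pair is the
    kcat knob instead.  Returns ``(rates, fixed_dims, report)``.
    """
    if rates is None:
        rates = default_rateset(scheme)
    crates, frozen = apply_constraints(rates, constraints)
    rates = crates
    frozen = set(frozen) | set(fixed or ())
    report = FitReport(seed=seed)
    tgt = {k: v for k, v in targets.numeric().items() if k.startswith("aa_")}
    if targets.k_chem is not None:
        tgt["k_chem"] = targets.k_chem
    present = {s.id for s in scheme.steps}
    flipflop = "prod_rel_d" in present

    sync = {}
    if tie_activation and "act" in present and "act_r" in present:
        if not {"act_r:kf", "act_r:kb"} & frozen:
            sync["act_r"] = rates["act"]
            frozen.update({"act_r:kf", "act_r:kb"})
    if flipflop and "act" in present and "act_2" in present:
        # site 2 has no tRNA bound: its activation follows the tRNA-free rates
        if not {"act_2:kf", "act_2:kb"} & frozen:
            sync["act_2"] = rates["act"]
    rates = rates.replace(**sync)

    # the aminoacylation turnover is set by the product-release rates: the
    # monomer's direct/ATP-assisted release, or the site-1 release gated by
    # second-site activation in the flip-flop dimer
    kcat_knobs = [("prod_rel_dp", "kf"), ("prod_rel_d", "kf")] if flipflop \
        else [("prod_rel", "kf"), ("prod_rel_t", "kf")]
    trna_steps = [s for s in ("trna_bind_0", "trna_bind_a", "trna_bind_t",
                              "trna_bind_at", "trna_bind_d") if s in present]

    which = {"aa"} | ({"k_chem"} if "k_chem" in tgt else set())

    def pred(r):
        m = _SchemeModel(scheme, r, sites=sites, trna_required=trna_required)
        return predict_observables(m, which=which)

    best = None
    for it in range(18):
        p = pred(rates)
        loss = _loss(p, tgt)
        report.loss_trace.append(loss)
        if best is None or loss < best[0]:
            best = (loss, rates)
        if _within(p, tgt, 0.03):
            break
        new = rates
        if "aa_kcat" in tgt and p.get("aa_kcat"):
            f = _clip(tgt["aa_kcat"] / p["aa_kcat"])
            for sid, dims in kcat_knobs:
                if sid in present:
                    new = _scale(new, frozen, sid,
                                 f_kf=f, f_kb=f if dims == "both" else 1.0)
        if "aa_km_trna" in tgt and p.get("aa_km_trna"):
            # capture is near-committed, so Km_trna ~ kcat / k_on; the
            # adenylate-state on-rate is the primary knob, with the weaker
            # substrate-free-state on-rates held at a fixed fraction of it
            # (early tRNA binding routes flux through the slow-capture
            # branch and degrades k_chem if allowed to dominate)
            f_on = _clip(p["aa_km_trna"] / tgt["aa_km_trna"])
            if "trna_bind_d" in present:
                new = _scale(new, frozen, "trna_bind_d", f_kf=f_on)
                kon_d = new.kf("trna_bind_d")
                for sid in trna_steps:
                    if sid != "trna_bind_d" and f"{sid}:kf" not in frozen:
                        new = new.replace(**{sid: (0.3 * kon_d, new.kb(sid))})
            else:
                for sid in trna_steps:
                    new = _scale(new, frozen, sid, f_kf=f_on)
        if "aa_km_aa" in tgt and p.get("aa_km_aa"):
            # binding equilibrates fast relative to activation: the
            # off-rates (effective K_d with tRNA bound) set Km_aa.  The
            # off-rate is capped relative to the activation rate so the
            # tRNA-bound branch never becomes a kinetic dead end (Km_aa
            # saturates there anyway, via the tRNA-free capture path)
            f_off = _clip(tgt["aa_km_aa"] / p["aa_km_aa"])
            cap = 60.0 * new.kf("act_r") if "act_r" in present else 2.0e4
            for sid in ("aa_bind_r", "aa_bind_rt"):
                if sid in present and f"{sid}:kb" not in frozen:
                    kf, kb = new[sid]
                    if f_off < 1.0 and kb < 1e-3 * cap and \
                            f"{sid}:kf" not in frozen:
                        # off-rate floored: a very low Km_aa needs a faster
                        # on-rate instead
                        kf = kf / f_off
                    new = new.replace(**{sid: (kf, min(kb * f_off, cap))})
        if "aa_km_atp" in tgt and p.get("aa_km_atp"):
            f = _clip(tgt["aa_km_atp"] / p["aa_km_atp"])
            for sid in ("atp_bind_r", "atp_bind_ra"):
                if sid in present:
                    new = _scale(new, frozen, sid, f_kb=f)
        if "k_chem" in tgt and p.get("k_chem"):
            # composite chemistry is capture-limited: speed both directions
            # of amino-acid binding in the tRNA branch (K_d preserved, so
            # the Km_aa rule above is not undone)
            f = _clip((tgt["k_chem"] / p["k_chem"]) ** 0.5)
            for sid in ("aa_bind_r", "aa_bind_rt"):
                if sid in present:
                    new = _scale(new, frozen, sid, f_kf=f, f_kb=f)
        rates = new

    def burst_amplitude(r):
        m = _SchemeModel(scheme, r, sites=sites, trna_required=trna_required)
        try:
            return run_burst_assay(m, method="ode").amplitude_per_site
        except (AssayError, EstimatorError):
            return None

    def burst_hinge(amp):
        # push the amplitude clear of the 0.5/site decision boundary
        if targets.burst is None or amp is None:
            return 25.0 if targets.burst is not None and amp is None else 0.0
        if targets.burst:
            return 160.0 * max(0.0, 0.53 - amp) ** 2
        return 160.0 * max(0.0, amp - 0.40) ** 2

    p = pred(rates)
    amp = burst_amplitude(rates) if targets.burst is not None else None
    if not _within(p, tgt, targets.tolerance) or burst_hinge(amp) > 0:
        knobs = kcat_knobs + [("trna_bind_d", "kf")] + \
            [("aa_bind_r", "kb"), ("aa_bind_rt", "kb"), ("amp_rel", "kf")]

        # the turnover number is the headline observable; the burst margin
        # is bought preferentially with the softer Km/k_chem targets
        w = {"aa_kcat": 10.0, "aa_km_trna": 2.0, "k_chem": 0.5}

        def loss_fn(r):
            return _loss(pred(r), tgt, w) + burst_hinge(
                burst_amplitude(r) if targets.burst is not None else None)

        rates = _random_refine(rates, frozen, loss_fn, report, seed, knobs,
                               budget=100, sigma=0.12)
        p = pred(rates)
        amp = burst_amplitude(rates) if targets.burst is not None else None
    # k_chem is a soft consistency observable (k_chem ~ k_tran when binding
    # and activation are fast); the hard gate is the ratio band, not the
    # pointwise tolerance
    tgt_strict = {k: v for k, v in tgt.items() if k != "k_chem"}
    if not _within(p, tgt_strict, targets.tolerance):
        report.fail(f"aminoacylation observables {p} outside tolerance of {tgt_strict}")
    if "k_chem" in tgt and targets.k_tran:
        m = _SchemeModel(scheme, rates, sites=sites, trna_required=trna_required)
        k_tran_model = predict_observables(m, which={"k_tran"}).get(
            "k_tran", targets.k_tran)
        ratio = (p.get("k_chem") or 0.0) / k_tran_model
        if not (0.8 <= ratio <= 1.3):
            report.fail(f"k_chem/k_tran ratio {ratio:.2f} outside [0.8, 1.3]")

    if targets.burst is not None:
        got = None if amp is None else (amp >= 0.5)
        if got is None:
            report.fail("burst phenotype could not be evaluated")
        elif got != targets.burst:
            report.fail(f"burst phenotype {got} (amplitude/site {amp:.3f}) "
                        f"!= expected {targets.burst}")
        else:
            report.log(f"burst phenotype {got} as expected "
                       f"(amplitude/site {amp:.3f})")

    fixed_out = set(frozen)
    for st in scheme.steps:
        fixed_out.update({f"{st.id}:kf", f"{st.id}:kb"})
    report.fixed = fixed_out
    report.log(f"stage3: aminoacylation observables {p}")
    return rates, fixed_out, report


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def fit_enzyme(enzyme_spec, targets: FitTargets, constraints=(),
               seed: int = 0):
    """Run the three stages for one enzyme; returns (EnzymeModel, FitReport).

    ``enzyme_spec`` is an enzyme name (one of the 20 E. coli AARSs) or a
    mapping with keys ``name``, ``variant``, ``class`` and optionally
    ``sites``.  The report's ``success`` flag is False when any stage
    could not reach its targets within tolerance.
    """
    if isinstance(enzyme_spec, str):
        variant, flag = sch.canonical_variant(enzyme_spec)
        name = enzyme_spec
        klass = "I" if name in sch.CLASS_I else "II"
        sites = 2 if variant == sch.CLASS2_FLIPFLOP else 1
    else:
        name = enzyme_spec["name"]
        variant = enzyme_spec["variant"]
        klass = enzyme_spec.get("class", "I")
        sites = enzyme_spec.get("sites",
                                2 if variant == sch.CLASS2_FLIPFLOP else 1)
        flag = enzyme_spec.get("trna_required",
                               variant == sch.CLASS1_TRNA_REQUIRED)
    scheme = sch.build_scheme(variant, flag)
    report = FitReport(seed=seed)

    rates = default_rateset(scheme)
    fixed: set = set()
    if targets.k_tran is not None:
        rates, fixed, r1 = fit_stage_single_turnover(
            scheme, targets, constraints, seed=seed, rates=rates)
        report.messages += r1.messages
        report.loss_trace += r1.loss_trace
        report.success &= r1.success
    if targets.pp_kcat is not None and not flag:
        rates, fixed, r2 = fit_stage_pp_exchange(
            scheme, targets, constraints, rates=rates, fixed=fixed,
            seed=seed + 1)
        report.messages += r2.messages
        report.loss_trace += r2.loss_trace
        report.success &= r2.success
    rates, fixed, r3 = fit_stage_aminoacylation(
        scheme, targets, constraints, rates=rates, fixed=fixed, seed=seed + 2,
        sites=sites, trna_required=flag)
    report.messages += r3.messages
    report.loss_trace += r3.loss_trace
    report.success &= r3.success
    report.fixed = fixed

    model = EnzymeModel(name=name, klass=klass, variant=variant, rates=rates,
                        sites=sites, trna_required=flag)
    return model, report
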