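"""In-silico versions of the three classical AARS kinetics assays.

* :func:`run_km_assay` -- pyrophosphate exchange or aminoacylation at a
  grid of substrate concentrations; each point is the mean initial
  velocity over replicate stochastic runs, and the grid is summarised by
  a Woolf-Hanes fit (kcat, Km).
* :func:`run_single_turnover` -- enzyme in ten-fold excess over tRNA;
  the aa-tRNA appearance curve is fit to A(1 - exp(-B t)), giving the
  transfer rate k_tran (pre-formed adenylate) or the composite chemistry
  rate k_chem (all substrates mixed at t = 0).
* :func:`run_burst_assay` -- pre-steady-state product time course at
  0.25 uM enzyme; class I enzymes show an initial burst of aa-tRNA
  formation faster than kcat, class II (flip-flop) enzymes do not.

Default concentrations follow the standard protocols: pyrophosphate
exchange at [PPi] = 2 mM, [ATP] = 5 mM, [AA] = 0.5 mM, [E] = 10 nM;
aminoacylation adds [tRNA] = 10 uM; single turnover uses [tRNA] = 5 uM
with [E] = 50 uM; the burst assay uses [E] = 0.25 uM and [tRNA] = 10 uM.
Each assay may be run with the exact stochastic simulator
(``method='ssa'``) or with the deterministic stationary-state solver
(``method='ode'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import schemes as sch
from .estimators import (EstimatorError, BurstResult, ExpFit, MMFit,
                         detect_burst, fit_exponential, woolf_hanes_fit)
from .simulate import (AssayConditions, Velocity, compile_system,
                       initial_velocity, simulate_ode, simulate_ssa,
                       steady_state_velocity)

__all__ = ["VelocityPoint", "AssayError", "run_km_assay",
           "run_single_turnover", "run_burst_assay",
           "pp_exchange_conditions", "aminoacylation_conditions"]

_VARIED = {"AA": sch.AA, "ATP": sch.ATP, "tRNA": sch.TRNA, "PPi": sch.PPI,
           sch.AA: sch.AA, sch.ATP: sch.ATP, sch.TRNA: sch.TRNA,
           sch.PPI: sch.PPI}


class AssayError(RuntimeError):
    pass


@dataclass
class VelocityPoint:
    """Mean initial velocity at one substrate concentration."""

    concentration: float       # uM of the varied substrate
    velocity: float            # s^-1 per enzyme, mean over replicates
    sd: float                  # standard deviation over replicates
    n_replicates: int = 1

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_replicates < 2 and self.sd > 0:
            raise ValueError("a reported sd needs at least 2 replicates")


def pp_exchange_conditions(**overrides) -> AssayConditions:
    base = dict(concentrations={sch.ATP: 5000.0, sch.AA: 500.0,
                                sch.PPI: 2000.0},
                enzyme_conc=0.01, enzyme_copies=100, duration=1.0)
    base.update(overrides)
    return AssayConditions(**base)


def aminoacylation_conditions(**overrides) -> AssayConditions:
    base = dict(concentrations={sch.ATP: 5000.0, sch.AA: 500.0,
                                sch.TRNA: 10.0},
                enzyme_conc=0.01, enzyme_copies=50, duration=12.0)
    base.update(overrides)
    return AssayConditions(**base)


def _split(model):
    if hasattr(model, "scheme") and hasattr(model, "rates"):
        return model.scheme, model.rates
    return model


def _assay_parts(model, assay: str):
    """(scheme, rates, default conditions, velocity mode) for an assay."""
    scheme, rates = _split(model)
    if assay == "pp_exchange":
        if getattr(model, "trna_required", False):
            raise AssayError(
                f"{model.name} requires tRNA for activation; the tRNA-free "
                "pyrophosphate-exchange assay is undefined")
        if scheme.variant != sch.PP_EXCHANGE and "act" in {s.id for s in scheme.steps}:
            scheme = sch.build_pp_exchange_scheme()
        return scheme, rates, pp_exchange_conditions(), "pp_exchange"
    if assay == "aminoacylation":
        return scheme, rates, aminoacylation_conditions(), "product"
    raise AssayError(f"unknown assay {assay!r}")


def _pilot_km(scheme, rates, conditions, species, mode) -> float:
    """Coarse deterministic scan for the half-saturation concentration."""
    grid = np.logspace(-2.5, 4.5, 29)
    v = np.array([steady_state_velocity(scheme, rates,
                                        conditions.with_conc(species, c), mode)
                  for c in grid])
    vmax = v.max()
    if vmax <= 0:
        raise AssayError("pilot scan found zero velocity everywhere")
    above = np.nonzero(v >= 0.5 * vmax)[0]
    i = above[0]
    if i == 0:
        return float(grid[0])
    # log-linear interpolation of the half-max crossing
    c0, c1 = grid[i - 1], grid[i]
    v0, v1 = v[i - 1], v[i]
    f = (0.5 * vmax - v0) / (v1 - v0)
    return float(np.exp(np.log(c0) + f * (np.log(c1) - np.log(c0))))


def _measure_velocity(scheme, rates, cond, mode, method, replicates, seed,
                      duration, n_samples):
    if method == "ode":
        return float(steady_state_velocity(scheme, rates, cond, mode)), 0.0, 1
    system = compile_system(scheme, rates, cond)
    vals = []
    for rep in range(replicates):
        traj = simulate_ssa(None, cond, duration=duration,
                            seed=(seed * 1000003 + rep) % (2 ** 31),
                            n_samples=n_samples, system=system)
        vals.append(float(initial_velocity(traj, mode)))
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if replicates > 1 else 0.0
    return float(vals.mean()), sd, replicates


def run_km_assay(model, assay: str, varied: str, grid=None, replicates: int = 10,
                 seed: int = 0, method: str = "ssa",
                 conditions: AssayConditions | None = None):
    """Measure kcat and Km for one substrate.

    Returns ``(points, fit)``: the per-concentration
    :class:`VelocityPoint` list and the Woolf-Hanes :class:`MMFit`.  With
    ``grid=None`` a coarse deterministic pilot scan estimates Km and the
    grid {0.2, 0.5, 1, 2, 5} x Km is used, giving the Hanes regression
    leverage on both sides of Km.
    """
    species = _VARIED.get(varied)
    if species is None:
        raise AssayError(f"cannot vary {varied!r}")
    scheme, rates, cond, mode = _assay_parts(model, assay)
    if conditions is not None:
        cond = conditions
    if grid is None:
        km_est = _pilot_km(scheme, rates, cond, species, mode)
        grid = np.array([0.2, 0.5, 1.0, 2.0, 5.0]) * km_est
    grid = np.asarray(grid, float)
    if len(grid) < 5:
        raise AssayError("concentration grid needs at least 5 points")

    n_samples = 200 if assay == "pp_exchange" else 400
    points = []
    for gi, conc in enumerate(grid):
        c = cond.with_conc(species, float(conc))
        v, sd, n = _measure_velocity(scheme, rates, c, mode, method,
                                     replicates, seed * 101 + gi,
                                     c.duration, n_samples)
        points.append(VelocityPoint(float(conc), v, sd, n))

    fit = woolf_hanes_fit(points)
    vels = np.array([p.velocity for p in points])
    if fit.valid and vels[-1] < 1.5 * vels[0]:
        fit.diagnostics = "grid saturating everywhere: Km poorly identified"
    return points, fit


def run_single_turnover(model, kind: str = "transfer", seed: int = 0,
                        method: str = "ssa", trna_copies: int = 500,
                        duration: float | None = None) -> ExpFit:
    """Single-turnover assay: enzyme ten-fold over tRNA.

    ``kind='transfer'`` starts every enzyme as the isolated
    enzyme-adenylate complex and measures the transfer rate k_tran;
    ``kind='chem'`` mixes free enzyme with ATP, amino acid and tRNA
    simultaneously and measures the composite chemistry rate k_chem.
    """
    full_scheme, rates = _split(model)
    if kind == "transfer":
        scheme = sch.build_single_turnover_scheme()
        start = "S5"
        conc = {sch.TRNA: 5.0}
        # flip-flop models have no stand-alone product-release step: the
        # charged tRNA stays bound until a second-site activation, which
        # cannot happen without ATP, so release is silent in this assay
        missing = {s.id for s in scheme.steps} - set(rates)
        if missing:
            rates = rates.replace(**{sid: (0.0, 0.0) for sid in missing})
    elif kind == "chem":
        scheme = full_scheme
        start = scheme.start_label
        conc = {sch.TRNA: 5.0, sch.ATP: 5000.0, sch.AA: 500.0}
    else:
        raise AssayError(f"unknown single-turnover kind {kind!r}")

    volume = trna_copies / (5.0 * 6.02214e17)
    cond = AssayConditions(concentrations=conc, bath={sch.TRNA: False},
                           enzyme_conc=50.0, volume=volume, duration=1.0)
    if cond.enzyme_copies < 10 * trna_copies:
        raise AssayError("single-turnover needs >= 10x enzyme over tRNA")

    if duration is None:
        # run until the charging curve plateaus (>=98% of tRNA consumed
        # or the curve stops growing)
        duration = 0.5
        for _ in range(6):
            traj = simulate_ode((scheme, rates), cond, duration=duration,
                                start_state=start, n_samples=200)
            if traj.product[-1] >= 0.98 * trna_copies or \
               traj.product[-1] < 1.02 * traj.product[len(traj.times) // 2]:
                break
            duration *= 4.0
    if method == "ode":
        traj = simulate_ode((scheme, rates), cond, duration=duration,
                            start_state=start, n_samples=300)
    else:
        traj = simulate_ssa((scheme, rates), cond, duration=duration,
                            seed=seed, start_state=start, n_samples=300)
    fit = fit_exponential(traj.times, traj.product)
    if fit.amplitude > 1.1 * trna_copies:
        raise EstimatorError(
            f"fitted amplitude {fit.amplitude:.1f} exceeds total tRNA "
            f"{trna_copies} by more than 10%")
    return fit


def run_burst_assay(model, seed: int = 0, method: str = "ssa",
                    duration: float | None = None,
                    enzyme_copies: int = 500,
                    replicates: int = 10) -> BurstResult:
    """Pre-steady-state aminoacylation time course and burst call.

    Conditions: [AA] = 500 uM, [ATP] = 5 mM, [tRNA] = 10 uM,
    [E] = 0.25 uM.  The burst flag is set when the late-phase intercept
    amounts to at least half a product per catalytic site.  Stochastic
    runs average the product curve over ``replicates`` before the
    amplitude extrapolation (a cuvette holds ~1e11 enzymes, so the
    experimental curve is the ensemble mean; ``method='ode'`` evaluates
    that mean directly).
    """
    scheme, rates = _split(model)
    sites = getattr(model, "sites", 1)
    cond = AssayConditions(
        concentrations={sch.ATP: 5000.0, sch.AA: 500.0, sch.TRNA: 10.0},
        enzyme_conc=0.25, enzyme_copies=enzyme_copies)
    if duration is None:
        kcat = steady_state_velocity(scheme, rates, cond, "product")
        if kcat <= 0:
            raise AssayError("model produces no product under burst conditions")
        duration = max(2.0, 8.0 / kcat)
    n_samples = max(500, int(np.ceil(duration / 0.01)))
    if method == "ode":
        traj = simulate_ode((scheme, rates), cond, duration=duration,
                            n_samples=n_samples)
        return detect_burst(traj, cond.enzyme_copies, sites)
    system = compile_system(scheme, rates, cond)
    mean_product = None
    for rep in range(replicates):
        traj = simulate_ssa(None, cond, duration=duration,
                            seed=(seed * 1000003 + rep) % (2 ** 31),
                            n_samples=n_samples, system=system)
        y = traj.product.astype(float)
        mean_product = y if mean_product is None else mean_product + y
    mean_product /= replicates
    return detect_burst((traj.times, mean_product), cond.enzyme_copies, sites)
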