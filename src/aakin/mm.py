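"""Michaelis-Menten reduction of the full aminoacylation mechanism.

The full enzyme-state model is expensive inside whole-cell simulations;
its steady-state charging velocity is well approximated by the MM form
v = Vm [S] / (Km + [S]) with Vm = kcat [E0].  This module provides the
reduced model and the algebra around it:

* :func:`mm_velocity` / :func:`mm_multi_isoacceptor` -- the velocity law,
  including the competitive multi-isoacceptor form (ATP assumed
  saturating) v(i) = Vm * [AA]/(Kma+[AA]) * ([Ti]/Kmt(i)) /
  (1 + sum_j [Tj]/Kmt(j)).
* :func:`invert_mm_for_substrate` -- solve for the free substrate (e.g.
  uncharged tRNA) that sustains a given velocity.
* :func:`rescale_kcat` -- the rescaling identity: at fixed turnover r and
  free tRNA [Tu], kcat and Km_trna can be traded against each other,
  kcat_new = r (Km_new + [Tu]) / [Tu], leaving the operating point
  untouched.
* :func:`derive_mm_from_full_model` -- extract MMParams from a full
  kinetic model by running the aminoacylation Km assays.
* :func:`kcat_sufficiency` -- can an enzyme with these MM parameters
  sustain an in-vivo turnover demand (requires kcat > r), and what free
  uncharged tRNA pool that takes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assays import run_km_assay
from .schemes import EnzymeModel

__all__ = ["MMParams", "DemandPoint", "mm_velocity", "mm_multi_isoacceptor",
           "invert_mm_for_substrate", "rescale_kcat",
           "derive_mm_from_full_model", "kcat_sufficiency"]


@dataclass
class MMParams:
    """Reduced Michaelis-Menten description of one AARS."""

    kcat: float                        # s^-1
    km_aa: float                       # uM
    km_trna: list                      # uM, one per isoacceptor
    enzyme_total: float = 1.0          # uM (or copies; sets Vm scale)

    def __post_init__(self):
        self.km_trna = list(np.atleast_1d(self.km_trna).astype(float))
        if self.kcat <= 0 or self.km_aa <= 0 or self.enzyme_total <= 0 \
                or not self.km_trna or any(k <= 0 for k in self.km_trna):
            raise ValueError("MM parameters must be positive and non-empty")

    @property
    def vm(self) -> float:
        return self.kcat * self.enzyme_total


@dataclass
class DemandPoint:
    """An in-vivo operating point: required turnover and free pools."""

    r: float                           # s^-1 per enzyme
    free_trna: float = 0.0             # uM (uncharged)
    free_aa: float = np.inf            # uM

    def __post_init__(self):
        if self.r < 0 or self.free_trna < 0 or self.free_aa < 0:
            raise ValueError("demand quantities must be >= 0")


def mm_velocity(kcat: float, km: float, s: float) -> float:
    """Per-enzyme MM velocity kcat [S] / (Km + [S]) in s^-1."""
    if s < 0:
        raise ValueError("substrate concentration must be >= 0")
    return kcat * s / (km + s)


def mm_multi_isoacceptor(params: MMParams, aa: float, trna) -> np.ndarray:
    """Per-isoacceptor charging rates with competitive tRNA binding.

    ATP is assumed saturating; the isoacceptors share the enzyme through
    the common competition denominator 1 + sum_j [Tj]/Kmt(j).
    """
    t = np.atleast_1d(np.asarray(trna, float))
    kmt = np.asarray(params.km_trna, float)
    if t.shape != kmt.shape:
        raise ValueError(
            f"{t.size} tRNA concentrations for {kmt.size} isoacceptor Km values")
    if aa < 0 or np.any(t < 0):
        raise ValueError("concentrations must be >= 0")
    aa_frac = aa / (params.km_aa + aa) if np.isfinite(aa) else 1.0
    denom = 1.0 + float(np.sum(t / kmt))
    return params.kcat * aa_frac * (t / kmt) / denom


def invert_mm_for_substrate(kcat: float, km: float, v: float) -> float:
    """Free substrate concentration sustaining velocity ``v``: S = Km v/(kcat - v)."""
    if not (0.0 <= v < kcat):
        raise ValueError(f"velocity {v} must satisfy 0 <= v < kcat = {kcat}")
    return km * v / (kcat - v)


def rescale_kcat(r: float, t_u: float, km_new: float) -> float:
    """Rescaled kcat preserving the operating point (r, [Tu]) at a new Km.

    kcat_new = r (Km_new + [Tu]) / [Tu] is the unique kcat for which the
    MM velocity at substrate [Tu] with Michaelis constant Km_new equals
    the turnover r.
    """
    if r <= 0 or t_u <= 0 or km_new <= 0:
        raise ValueError("r, [Tu] and Km_new must be positive")
    return r * (km_new + t_u) / t_u


def derive_mm_from_full_model(model: EnzymeModel, seed: int = 0,
                              method: str = "ode",
                              enzyme_total: float = 1.0) -> MMParams:
    """MM parameters of a full kinetic model via the aminoacylation assays.

    Runs the Km assay varying tRNA (kcat, Km_trna) and varying amino acid
    (Km_aa) and packages the Woolf-Hanes fits.  ``method='ssa'`` uses the
    stochastic protocol; the default deterministic pipeline is exact up
    to the Hanes-grid discretisation.
    """
    _, fit_t = run_km_assay(model, "aminoacylation", "tRNA", seed=seed,
                            method=method)
    _, fit_a = run_km_assay(model, "aminoacylation", "AA", seed=seed + 1,
                            method=method)
    if not (fit_t.valid and fit_a.valid):
        raise RuntimeError("aminoacylation assay fits invalid: "
                           f"{fit_t.diagnostics} {fit_a.diagnostics}")
    return MMParams(kcat=fit_t.kcat, km_aa=fit_a.km, km_trna=[fit_t.km],
                    enzyme_total=enzyme_total)


def kcat_sufficiency(params: MMParams, demand: DemandPoint,
                     isoacceptor: int = 0) -> dict:
    """Check kcat > r and report the free tRNA pool needed to meet demand.

    Feasibility requires the enzyme's maximal per-enzyme rate to exceed
    the in-vivo turnover requirement strictly; when feasible, the free
    uncharged tRNA concentration achieving v = r follows from the MM
    inversion (amino-acid saturation adjusted through the Km_aa factor).
    """
    kcat_eff = params.kcat
    if np.isfinite(demand.free_aa):
        kcat_eff = params.kcat * demand.free_aa / (params.km_aa + demand.free_aa)
    feasible = kcat_eff > demand.r
    out = {"feasible": bool(feasible), "kcat": params.kcat,
           "kcat_effective": kcat_eff, "r": demand.r}
    if feasible:
        out["required_Tu"] = invert_mm_for_substrate(
            kcat_eff, params.km_trna[isoacceptor], demand.r)
    else:
        out["deficit"] = demand.r - kcat_eff
    return out
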