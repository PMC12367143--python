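"""Cell-scale meta-analysis: turnover rates, consensus densities,
transcriptome reconstruction and a steady-state charging-demand simulation.

Proteomics measurements of AARS copy numbers vary strikingly between
groups; a consensus is extracted as the peak of a measurement-error-
weighted density ("violin"), p(y) = (1/A) sum_i exp(-(y-y_i)^2 / 2
sigma_i^2) with A = sum_i sqrt(2 pi) sigma_i so that p integrates to 1.
The in-vivo turnover requirement of a single enzyme is r_i = a_i / n_i
(amino-acid usage per cell over enzyme copies per cell), with usage
convertible between uM/s and molecules/s per cell through the cell
volume (602.214 molecules per um^3 per uM).

The transcriptome builder turns relative mRNA-seq abundances (RPKM) into
integer mRNA copy numbers: x(i) = RPKM(i)/sum RPKM, n(i) = alpha x(i)
with alpha set so the total nucleotide content matches the
Bremer-Dennis estimate for the growth rate of interest.

:func:`demand_charging_sim` couples each enzyme's full charging scheme
to a Poisson consumption drain that turns free charged tRNA back into
free uncharged tRNA at the demanded rate -- a deliberately simplified
stand-in for ribosomal consumption that still exposes the steady-state
partitioning of tRNA between free uncharged, free charged and
AARS-bound pools.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from . import schemes as sch
from .simulate import (MOLEC_PER_UM3_PER_UM, AssayConditions, compile_system,
                       simulate_ssa)

__all__ = ["ProteomicsMeasurement", "ViolinDensity", "TurnoverEstimate",
           "TranscriptomeSpec", "violin_density", "turnover_rate",
           "conc_rate_to_per_cell", "build_transcriptome", "codon_usage",
           "demand_charging_sim"]


# ---------------------------------------------------------------------------
# consensus turnover rates
# ---------------------------------------------------------------------------

@dataclass
class ProteomicsMeasurement:
    """One reported abundance/turnover value with its error.

    When no error is reported, a default 20% relative error is assumed.
    """

    value: float
    sigma: float | None = None
    source: str = ""
    mu: float | None = None        # growth rate, h^-1 (metadata)

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("measurement values must be positive")
        if self.sigma is None:
            self.sigma = 0.2 * self.value
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class ViolinDensity:
    grid: np.ndarray
    density: np.ndarray
    normalization: float           # A = sum_i sqrt(2 pi) sigma_i
    peak: float                    # grid argmax ("consensus" value)


def _as_measurements(measurements):
    out = []
    for m in measurements:
        if isinstance(m, ProteomicsMeasurement):
            out.append(m)
        else:
            y, s = m
            out.append(ProteomicsMeasurement(float(y), float(s)))
    return out


def violin_density(measurements, grid=None, n_grid: int = 2000) -> ViolinDensity:
    """Gaussian-mixture consensus density over a measurement set.

    The default evaluation grid spans [min(y) - 4 sigma_max,
    max(y) + 4 sigma_max]; the returned peak is the grid argmax, the most
    likely value to be observed in an experiment given the data.
    """
    ms = _as_measurements(measurements)
    if not ms:
        raise ValueError("need at least one measurement")
    y = np.array([m.value for m in ms])
    s = np.array([m.sigma for m in ms])
    if grid is None:
        pad = 4.0 * s.max()
        grid = np.linspace(y.min() - pad, y.max() + pad, n_grid)
    grid = np.asarray(grid, float)
    a = float(np.sum(np.sqrt(2.0 * np.pi) * s))
    dens = np.exp(-((grid[:, None] - y[None, :]) ** 2) / (2.0 * s[None, :] ** 2))
    p = dens.sum(axis=1) / a
    return ViolinDensity(grid=grid, density=p, normalization=a,
                         peak=float(grid[np.argmax(p)]))


@dataclass
class TurnoverEstimate:
    usage: float                   # a_i, molecules s^-1 per cell
    enzymes: float                 # n_i, copies per cell
    rate: float                    # r_i = a_i / n_i, s^-1 per enzyme


def turnover_rate(a: float, n: float) -> float:
    """Per-enzyme tRNA turnover r = a / n (usage over enzyme copies)."""
    if n <= 0:
        raise ValueError("enzyme count must be positive")
    if a < 0:
        raise ValueError("usage must be >= 0")
    return a / n


def conc_rate_to_per_cell(rate_um_per_s: float, volume_um3: float = 1.0) -> float:
    """Convert a uM/s rate to molecules/s in a cell of the given volume."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return rate_um_per_s * volume_um3 * MOLEC_PER_UM3_PER_UM


# ---------------------------------------------------------------------------
# transcriptome construction
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeSpec:
    ids: list
    rpkm: np.ndarray
    fractions: np.ndarray          # x(i), sums to 1
    alpha: float
    copies: np.ndarray             # integer n(i)
    lengths: np.ndarray            # nt
    total_nt_target: float

    @property
    def total_nt(self) -> float:
        return float(np.dot(self.copies, self.lengths))


def build_transcriptome(rpkm, lengths, total_nt_target: float) -> TranscriptomeSpec:
    """Integer mRNA copy numbers reproducing a total-nucleotide target.

    ``rpkm`` and ``lengths`` may be dicts keyed by mRNA id or parallel
    sequences.  Copies are alpha * x(i) rounded by largest remainder, so
    the realised nucleotide total stays within one mRNA length of the
    target.
    """
    if isinstance(rpkm, dict):
        ids = list(rpkm)
        r = np.array([float(rpkm[i]) for i in ids])
        ln = np.array([float(lengths[i]) for i in ids])
    else:
        r = np.asarray(rpkm, float)
        ln = np.asarray(lengths, float)
        ids = list(range(len(r)))
    if np.any(r < 0) or not np.any(r > 0):
        raise ValueError("RPKM values must be >= 0 with at least one positive")
    if np.any(ln <= 0):
        raise ValueError("mRNA lengths must be positive")
    if total_nt_target <= 0:
        raise ValueError("nucleotide target must be positive")
    x = r / r.sum()
    alpha = total_nt_target / float(np.dot(x, ln))
    raw = alpha * x
    copies = np.floor(raw).astype(np.int64)
    short = int(round(raw.sum())) - int(copies.sum())
    if short > 0:
        order = np.argsort(-(raw - np.floor(raw)))
        copies[order[:short]] += 1
    return TranscriptomeSpec(ids=ids, rpkm=r, fractions=x, alpha=alpha,
                             copies=copies, lengths=ln,
                             total_nt_target=float(total_nt_target))


def codon_usage(spec: TranscriptomeSpec, cds: dict) -> dict:
    """Copy-number-weighted codon counts and fractions of a transcriptome.

    ``cds`` maps mRNA id to an in-frame coding sequence (string or
    Bio.Seq); lengths must be divisible by 3.
    Returns ``{"counts": {codon: n}, "fractions": {codon: f}}``.
    """
    counts: Counter = Counter()
    for mrna_id, n in zip(spec.ids, spec.copies):
        if mrna_id not in cds:
            continue
        seq = str(cds[mrna_id]).upper()
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS {mrna_id!r} length {len(seq)} is not a "
                             "multiple of 3")
        for i in range(0, len(seq), 3):
            counts[seq[i:i + 3]] += int(n)
    total = sum(counts.values())
    fractions = {c: v / total for c, v in counts.items()} if total else {}
    return {"counts": dict(counts), "fractions": fractions}


# ---------------------------------------------------------------------------
# steady-state charging vs demand
# ---------------------------------------------------------------------------

def demand_charging_sim(models, demand, trna_totals, enzyme_copies,
                        pools=None, volume_um3: float = 1.0,
                        duration: float = 30.0, seed: int = 0,
                        n_samples: int = 400) -> dict:
    """Steady-state tRNA partitioning under a consumption demand.

    Each enzyme charges its own tRNA isoacceptor pool; a Poisson drain
    converts free charged tRNA back to free uncharged tRNA at the demand
    rate (molecules/s), standing in for ribosomal consumption.  Reports,
    per isoacceptor, the time-averaged partition over the final half of
    the run: charged fraction, fraction of tRNA bound to the enzyme, the
    realised charging velocity v (s^-1 per enzyme) against the demanded
    per-enzyme rate r, and an ``unsustainable`` flag when the drain
    cannot keep up (charged-pool collapse).
    """
    models = list(models)
    demand = list(np.atleast_1d(demand).astype(float))
    trna_totals = list(np.atleast_1d(trna_totals).astype(int))
    enzyme_copies = list(np.atleast_1d(enzyme_copies).astype(int))
    if not (len(models) == len(demand) == len(trna_totals) == len(enzyme_copies)):
        raise ValueError("models, demand, trna_totals and enzyme_copies "
                         "must have equal lengths")
    if any(d < 0 for d in demand) or any(t <= 0 for t in trna_totals):
        raise ValueError("demand must be >= 0 and tRNA totals positive")
    pools = dict(pools or {sch.ATP: 5000.0, sch.AA: 500.0})
    volume = volume_um3 * 1.0e-15  # litres

    reports = []
    for k, model in enumerate(models):
        scheme, rates = (model.scheme, model.rates) if hasattr(model, "scheme") \
            else model
        conc = dict(pools)
        conc[sch.TRNA] = trna_totals[k] / (volume_um3 * MOLEC_PER_UM3_PER_UM)
        cond = AssayConditions(
            concentrations=conc,
            bath={sch.TRNA: False, sch.AATRNA: False},
            enzyme_conc=0.0, enzyme_copies=enzyme_copies[k], volume=volume,
            duration=duration)
        system = compile_system(scheme, rates, cond)
        ti = sch.POOL_SPECIES.index(sch.TRNA)
        ai = sch.POOL_SPECIES.index(sch.AATRNA)
        if demand[k] > 0:
            system.add_reaction(rate=demand[k], cons=ai, rel=ti,
                                label=("consumption", "forward"))
        traj = simulate_ssa(None, cond, duration=duration,
                            seed=(seed * 7919 + k) % (2 ** 31),
                            n_samples=n_samples, system=system)

        # tRNA bound to the enzyme: ligand content of each state
        bound_per_state = np.array(
            [st.ligand_multiset()["R"] + st.ligand_multiset()["R*"]
             for st in scheme.states], float)
        bound_charged_per_state = np.array(
            [st.ligand_multiset()["R*"] for st in scheme.states], float)
        half = len(traj.times) // 2
        free_u = traj.pool_counts[half:, ti].mean()
        free_c = traj.pool_counts[half:, ai].mean()
        bound = (traj.state_counts[half:] @ bound_per_state).mean()
        bound_c = (traj.state_counts[half:] @ bound_charged_per_state).mean()
        total = trna_totals[k]

        t_half = traj.times[half:]
        prod_half = traj.product[half:]
        v = float(np.polyfit(t_half, prod_half, 1)[0]) / max(enzyme_copies[k], 1)
        drain_fired = 0.0
        if demand[k] > 0:
            drain_fired = float(traj.firings[-1, -1] - traj.firings[half, -1])
        realised_drain = drain_fired / (traj.times[-1] - traj.times[half])
        unsustainable = demand[k] > 0 and (
            realised_drain < 0.9 * demand[k] or
            free_c < 0.02 * total)

        reports.append({
            "enzyme": getattr(model, "name", f"model{k}"),
            "charged_fraction": (free_c + bound_c) / total,
            "free_uncharged": free_u,
            "free_charged": free_c,
            "bound_fraction": bound / total,
            "v": v,
            "r": demand[k] / max(enzyme_copies[k], 1),
            "unsustainable": bool(unsustainable),
            "trajectory": traj,
        })
    bound_total = sum(r["bound_fraction"] * t for r, t in zip(reports, trna_totals))
    return {
        "per_isoacceptor": reports,
        "bound_fraction_overall": bound_total / sum(trna_totals),
        "unsustainable": any(r["unsustainable"] for r in reports),
    }
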