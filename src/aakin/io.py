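"""Rate-table I/O, packaged enzyme models and synthetic fixtures.

Rate tables are TSV with columns ``enzyme, step_id, k_forward, k_backward,
units``.  The units column records the *forward* direction convention:
``uM-1.s-1`` for pool-consuming (binding) steps and ``s-1`` otherwise;
the backward convention follows from the scheme (a binding step's reverse
is unimolecular, a release step's reverse is bimolecular).

The package ships fitted rate tables for cysRS (class I monomer) and
hisRS (class II flip-flop dimer) under ``aakin/data``, produced by the
staged fitting procedure in :mod:`aakin.fitting` against consensus
in-vitro kcat/Km/k_tran targets, together with those target values.

Fixture generators (:func:`make_mm_oracle_fixture`,
:func:`make_synthetic_enzyme`) build fully specified mechanisms with
known observables for end-to-end calibration of the assay and fitting
pipelines; they are pure functions of their arguments.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from . import schemes as sch
from .schemes import EnzymeModel, RateSet, ReactionScheme

__all__ = ["read_rate_table", "write_rate_table", "load_builtin_enzyme",
           "builtin_targets", "make_mm_oracle_fixture", "make_synthetic_enzyme",
           "RateTableError"]

_UNI = "s-1"
_BI = "uM-1.s-1"


class RateTableError(ValueError):
    pass


def _known_steps() -> dict:
    """step_id -> ReactionStep over every scheme variant."""
    steps = {}
    for variant in (sch.CLASS1_MONOMER, sch.CLASS2_FLIPFLOP, sch.PP_EXCHANGE,
                    sch.SINGLE_TURNOVER):
        for st in sch.build_scheme(variant).steps:
            steps.setdefault(st.id, st)
    return steps


def read_rate_table(path) -> dict:
    """Parse a rate TSV into ``{enzyme: RateSet}`` with validation.

    Unknown step ids, negative rates and units inconsistent with the
    step's molecularity are rejected with the offending row named.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"enzyme", "step_id", "k_forward", "k_backward", "units"}
    if not required.issubset(df.columns):
        raise RateTableError(f"rate table must have columns {sorted(required)}")
    known = _known_steps()
    out: dict = {}
    for row in df.itertuples():
        i = row.Index
        st = known.get(row.step_id)
        if st is None:
            raise RateTableError(f"row {i}: unknown step id {row.step_id!r}")
        kf, kb = float(row.k_forward), float(row.k_backward)
        if kf < 0 or kb < 0:
            raise RateTableError(f"row {i} ({row.enzyme}/{row.step_id}): negative rate")
        expect = _BI if st.forward_bimolecular else _UNI
        if str(row.units) != expect:
            raise RateTableError(
                f"row {i} ({row.enzyme}/{row.step_id}): units {row.units!r}, "
                f"expected {expect!r} for a "
                f"{st.molecularity('forward')} forward step")
        out.setdefault(row.enzyme, {})[row.step_id] = (kf, kb)
    return {enz: RateSet(d) for enz, d in out.items()}


def write_rate_table(path, entries) -> None:
    """Write ``{enzyme: (ReactionScheme, RateSet)}`` (or EnzymeModels) as TSV."""
    rows = []
    if isinstance(entries, dict):
        items = entries.items()
    else:
        items = [(m.name, (m.scheme, m.rates)) for m in entries]
    for enzyme, (scheme, rates) in items:
        for st in scheme.steps:
            kf, kb = rates[st.id]
            rows.append(dict(enzyme=enzyme, step_id=st.id, k_forward=kf,
                             k_backward=kb,
                             units=_BI if st.forward_bimolecular else _UNI))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged enzyme models
# ---------------------------------------------------------------------------

def _data(name: str):
    return resources.files("aakin").joinpath("data", name)


def builtin_targets(name: str) -> dict:
    """Consensus in-vitro observable targets for a packaged enzyme."""
    meta = json.loads(_data("enzymes.json").read_text())
    if name not in meta:
        raise KeyError(f"no packaged targets for {name!r}")
    return meta[name]


def load_builtin_enzyme(name: str) -> EnzymeModel:
    """Load a packaged fitted enzyme model (``cysRS`` or ``hisRS``)."""
    meta = builtin_targets(name)
    with resources.as_file(_data("rates.tsv")) as p:
        tables = read_rate_table(p)
    if name not in tables:
        raise KeyError(f"no packaged rates for {name!r}")
    variant, flag = sch.canonical_variant(name)
    return EnzymeModel(name=name, klass=meta["class"], variant=variant,
                       rates=tables[name], sites=meta.get("sites", 1),
                       trna_required=flag)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_mm_oracle_fixture(kcat: float, km: float, seed: int = 0):
    """A minimal 2-state charging mechanism with exact MM kinetics.

    E + tRNA <-> E.tRNA -> E + aa-tRNA, with k_off = kcat so that the
    Briggs-Haldane constant (k_off + kcat)/k_on equals ``km`` exactly.
    Used to calibrate the assay/estimator pipeline end to end: the
    steady-state velocity is kcat [T] / (Km + [T]) in closed form.
    """
    if kcat <= 0 or km <= 0:
        raise ValueError("kcat and Km must be positive")
    k_off = kcat
    k_on = (k_off + kcat) / km
    states = (
        sch.EnzymeState("S0", (frozenset(),)),
        sch.EnzymeState("S6", (frozenset({"R"}),)),
    )
    steps = (
        sch.ReactionStep("bind", "S0", "S6", "binding", consumes=sch.TRNA),
        sch.ReactionStep("cat", "S6", "S0", "conversion", releases=sch.AATRNA),
    )
    scheme = ReactionScheme(variant="mm_oracle", states=states, steps=steps,
                            product_steps=("cat",))
    rates = RateSet({"bind": (k_on, k_off), "cat": (kcat, 0.0)})
    return scheme, rates


def make_synthetic_enzyme(class_variant: str = sch.CLASS1_MONOMER,
                          seed: int = 0):
    """A random but physically plausible enzyme with known observables.

    Rates are drawn log-uniformly around the package defaults (within a
    factor of 3); the returned targets are the enzyme's own simulated
    observables, so fitting them back is a ground-truth recovery problem.
    Returns ``(EnzymeModel, FitTargets)``.
    """
    import numpy as np

    from .fitting import FitTargets, default_rateset, predict_observables

    rng = np.random.default_rng(seed)
    scheme = sch.build_scheme(class_variant)
    base = default_rateset(scheme)
    jitter = {}
    for sid, (kf, kb) in base.items():
        jf = float(np.exp(rng.uniform(-np.log(3.0), np.log(3.0))))
        jb = float(np.exp(rng.uniform(-np.log(3.0), np.log(3.0))))
        jitter[sid] = (kf * jf, kb * jb)
    rates = RateSet(jitter)
    klass = "II" if class_variant == sch.CLASS2_FLIPFLOP else "I"
    model = EnzymeModel(name=f"syn{seed}", klass=klass, variant=class_variant,
                        rates=rates,
                        sites=2 if class_variant == sch.CLASS2_FLIPFLOP else 1)
    obs = predict_observables(model)
    targets = FitTargets(
        pp_kcat=obs.get("pp_kcat"), pp_km_aa=obs.get("pp_km_aa"),
        pp_km_atp=obs.get("pp_km_atp"), aa_kcat=obs.get("aa_kcat"),
        aa_km_aa=obs.get("aa_km_aa"), aa_km_trna=obs.get("aa_km_trna"),
        k_tran=obs.get("k_tran"))
    return model, targets
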