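"""Enzyme-state reaction schemes for aminoacyl-tRNA synthetase (AARS) kinetics.

An AARS charges its tRNA in two catalytic steps: *activation* (amino acid +
ATP -> enzyme-bound aminoacyl-adenylate + PPi) and *transfer* (adenylate +
tRNA -> aa-tRNA + AMP).  This module encodes the full multi-state reaction
graphs used to simulate that chemistry:

* ``class1_monomer`` -- the 16-state scheme (S0..S15) for monomeric class I
  enzymes (and the half-of-sites class I dimers tyrRS/trpRS).  Substrates
  bind in random order, adenylate can form with or without tRNA bound, PPi
  may be released before or after transfer (dual path S10->S11->S13 vs
  S10->S12->S13), and ATP can bind before the charged tRNA leaves
  (S14->S15), so that ATP competes with AMP for the product-bound enzyme.
* ``class1_tRNA_required`` -- as above but adenylate formation from
  tRNA-free states is absent (argRS, gluRS, glnRS require tRNA to
  activate).
* ``class2_flipflop`` -- the half-of-sites "flip-flop" dimer scheme for
  class II enzymes and metRS: the class I path runs in site 1, the charged
  tRNA stays bound while a fresh adenylate forms in site 2, and only then
  is the site-1 product released.
* ``pp_exchange`` -- the 6-state tRNA-free subscheme probed by the
  pyrophosphate-exchange assay (12 rate parameters).
* ``single_turnover`` -- the adenylate-to-product subscheme probed by
  single-turnover transfer assays (8 rate parameters).

States are named S0, S1, ... and carry an explicit ligand composition per
catalytic site using the abbreviations T = ATP, M = AMP, P = PPi, A = amino
acid, D = aminoacyl-adenylate, R = tRNA, R* = aa-tRNA.  Every kinetic step
is reversible; rate constants live in a separate :class:`RateSet` so one
graph serves many enzymes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ATP", "AA", "PPI", "AMP", "TRNA", "AATRNA", "POOL_SPECIES",
    "EnzymeState", "ReactionStep", "ReactionScheme", "RateSet", "EnzymeModel",
    "SchemeError",
    "build_scheme", "build_pp_exchange_scheme", "build_single_turnover_scheme",
    "dissociation_constant", "canonical_variant",
    "CLASS1_MONOMER", "CLASS1_TRNA_REQUIRED", "CLASS2_FLIPFLOP",
    "PP_EXCHANGE", "SINGLE_TURNOVER",
]

# ---------------------------------------------------------------------------
# pool species and ligand codes
# ---------------------------------------------------------------------------

ATP = "ATP"
AA = "AA"
PPI = "PPi"
AMP = "AMP"
TRNA = "tRNA"
AATRNA = "aa-tRNA"

#: Order used everywhere a pool vector is indexed.
POOL_SPECIES = (ATP, AA, PPI, AMP, TRNA, AATRNA)

#: Ligand code deposited on the enzyme when a pool species binds.
POOL_TO_LIGAND = {ATP: "T", AA: "A", PPI: "P", AMP: "M", TRNA: "R", AATRNA: "R*"}

#: A site holds at most one member of each of these groups.
_EXCLUSIVE_GROUPS = (frozenset({"R", "R*"}), frozenset({"T", "M", "D"}))

CLASS1_MONOMER = "class1_monomer"
CLASS1_TRNA_REQUIRED = "class1_tRNA_required"
CLASS2_FLIPFLOP = "class2_flipflop"
PP_EXCHANGE = "pp_exchange"
SINGLE_TURNOVER = "single_turnover"

_VARIANTS = (CLASS1_MONOMER, CLASS1_TRNA_REQUIRED, CLASS2_FLIPFLOP,
             PP_EXCHANGE, SINGLE_TURNOVER)


class SchemeError(ValueError):
    """Raised for malformed schemes or invalid scheme requests."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnzymeState:
    """A labelled enzyme state: one ligand set per catalytic site."""

    label: str
    composition: tuple[frozenset, ...]  # one frozenset of ligand codes per site

    @property
    def site_count(self) -> int:
        return len(self.composition)

    def validate(self) -> None:
        for site in self.composition:
            for group in _EXCLUSIVE_GROUPS:
                if len(site & group) > 1:
                    raise SchemeError(
                        f"state {self.label}: site holds more than one of {sorted(group)}")

    def ligand_multiset(self) -> Counter:
        c: Counter = Counter()
        for site in self.composition:
            c.update(site)
        return c


@dataclass(frozen=True)
class ReactionStep:
    """A reversible kinetic step between two enzyme states.

    The *forward* direction may consume one molecule from a pool (binding)
    and/or release one (dissociation); the backward direction reverses the
    exchange.  ``kind`` tags the chemistry for validation: ``binding``
    (ligand arrives from a pool), ``release`` (ligand leaves to a pool),
    ``activation`` (A + T -> D + P on the enzyme) or ``transfer``
    (D + R -> M + R* on the enzyme).
    """

    id: str
    from_state: str
    to_state: str
    kind: str
    consumes: str | None = None   # pool species consumed by the forward step
    releases: str | None = None   # pool species released by the forward step
    site: int = 0                 # catalytic site the step acts on

    @property
    def forward_bimolecular(self) -> bool:
        return self.consumes is not None

    @property
    def backward_bimolecular(self) -> bool:
        return self.releases is not None

    def molecularity(self, direction: str = "forward") -> str:
        bim = self.forward_bimolecular if direction == "forward" else self.backward_bimolecular
        return "bimolecular-with-pool" if bim else "unimolecular"


@dataclass(frozen=True)
class ReactionScheme:
    """A validated enzyme-state graph with reversible steps.

    ``product_steps`` lists the step ids whose forward firing creates one
    aa-tRNA (the transfer steps); ``exchange_steps`` lists the activation
    steps whose *backward* firing converts adenylate + PPi back to ATP (the
    event counted by the pyrophosphate-exchange assay).
    """

    variant: str
    states: tuple[EnzymeState, ...]
    steps: tuple[ReactionStep, ...]
    start_label: str = "S0"
    product_steps: tuple[str, ...] = ()
    exchange_steps: tuple[str, ...] = ()

    # -- lookups ------------------------------------------------------------
    def state(self, label: str) -> EnzymeState:
        return self._by_label[label]

    @property
    def _by_label(self) -> dict:
        d = self.__dict__.get("_by_label_cache")
        if d is None:
            d = {s.label: s for s in self.states}
            self.__dict__["_by_label_cache"] = d
        return d

    def step(self, step_id: str) -> ReactionStep:
        for s in self.steps:
            if s.id == step_id:
                return s
        raise KeyError(step_id)

    @property
    def n_parameters(self) -> int:
        """Number of rate constants (a forward and a backward per step)."""
        return 2 * len(self.steps)

    @property
    def site_count(self) -> int:
        return self.states[0].site_count

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        labels = {s.label for s in self.states}
        if len(labels) != len(self.states):
            raise SchemeError("duplicate state labels")
        if self.start_label not in labels:
            raise SchemeError(f"start state {self.start_label} missing")
        ids = [st.id for st in self.steps]
        if len(set(ids)) != len(ids):
            raise SchemeError("duplicate step ids")
        for s in self.states:
            s.validate()
        for st in self.steps:
            if st.from_state not in labels or st.to_state not in labels:
                raise SchemeError(f"step {st.id}: dangling endpoint")
            self._check_step_chemistry(st)
        if not self.reachable_from_start() == labels:
            missing = labels - self.reachable_from_start()
            raise SchemeError(f"states unreachable from {self.start_label}: {sorted(missing)}")

    def _check_step_chemistry(self, st: ReactionStep) -> None:
        before = self.state(st.from_state).ligand_multiset()
        after = self.state(st.to_state).ligand_multiset()
        gained = dict(Counter(after) - Counter(before))
        lost = dict(Counter(before) - Counter(after))
        if st.kind == "binding":
            expect_g = {POOL_TO_LIGAND[st.consumes]: 1} if st.consumes else {}
            if gained != expect_g or lost:
                raise SchemeError(f"step {st.id}: binding stoichiometry broken")
        elif st.kind == "release":
            expect_l = {POOL_TO_LIGAND[st.releases]: 1} if st.releases else {}
            if lost != expect_l or gained:
                raise SchemeError(f"step {st.id}: release stoichiometry broken")
        elif st.kind == "activation":
            if gained != {"D": 1, "P": 1} or lost != {"A": 1, "T": 1}:
                raise SchemeError(f"step {st.id}: activation must convert A+T to D+P")
        elif st.kind == "transfer":
            if gained != {"M": 1, "R*": 1} or lost != {"D": 1, "R": 1}:
                raise SchemeError(f"step {st.id}: transfer must convert D+R to M+R*")
        elif st.kind == "conversion":
            pass  # lumped chemistry (oracle/toy mechanisms); not composition-checked
        else:
            raise SchemeError(f"step {st.id}: unknown kind {st.kind!r}")

    def reachable_from_start(self) -> set:
        adj: dict[str, list[str]] = {s.label: [] for s in self.states}
        for st in self.steps:
            adj[st.from_state].append(st.to_state)
            adj[st.to_state].append(st.from_state)
        seen = {self.start_label}
        frontier = [self.start_label]
        while frontier:
            nxt = []
            for lab in frontier:
                for nb in adj[lab]:
                    if nb not in seen:
                        seen.add(nb)
                        nxt.append(nb)
            frontier = nxt
        return seen

    # -- export -------------------------------------------------------------
    def to_edge_list(self) -> list[tuple]:
        """Plain-text friendly edge list (from, to, step id, pool exchange)."""
        rows = []
        for st in self.steps:
            pool = ""
            if st.consumes:
                pool += f"+{st.consumes}"
            if st.releases:
                pool += f"-{st.releases}"
            rows.append((st.from_state, st.to_state, st.id, pool))
        return rows


class RateSet(Mapping):
    """Forward/backward rate constants per step id.

    Units: unimolecular directions in s^-1, bimolecular (pool-consuming)
    directions in uM^-1 s^-1.  Behaves as a read-only mapping
    ``step_id -> (k_f, k_b)``.
    """

    def __init__(self, rates: Mapping[str, tuple]):
        clean = {}
        for sid, (kf, kb) in rates.items():
            kf = float(kf)
            kb = float(kb)
            if not (kf >= 0.0 and kb >= 0.0):
                raise ValueError(f"step {sid}: rates must be finite and >= 0")
            clean[sid] = (kf, kb)
        self._rates = clean

    def __getitem__(self, sid):
        return self._rates[sid]

    def __iter__(self):
        return iter(self._rates)

    def __len__(self):
        return len(self._rates)

    def kf(self, sid: str) -> float:
        return self._rates[sid][0]

    def kb(self, sid: str) -> float:
        return self._rates[sid][1]

    def replace(self, **updates) -> "RateSet":
        """Return a copy with ``step_id=(kf, kb)`` entries replaced."""
        d = dict(self._rates)
        d.update(updates)
        return RateSet(d)

    def to_dict(self) -> dict:
        return dict(self._rates)

    @property
    def n_parameters(self) -> int:
        return 2 * len(self._rates)


def dissociation_constant(rates: RateSet, step_id: str) -> float:
    """K_d = k_b / k_f for a binding step, in uM.

    Follows the convention K2d = k2b / k2f used for substrate binding;
    k_f = 0 leaves K_d undefined and raises.
    """
    kf, kb = rates[step_id]
    if kf == 0.0:
        raise ValueError(f"step {step_id}: K_d undefined for k_f = 0")
    return kb / kf


# ---------------------------------------------------------------------------
# enzyme catalogue
# ---------------------------------------------------------------------------

#: class I enzymes whose activation step requires bound tRNA
TRNA_REQUIRED_ENZYMES = frozenset({"argRS", "gluRS", "glnRS"})

CLASS_I = frozenset({"cysRS", "argRS", "valRS", "ileRS", "leuRS", "glnRS",
                     "gluRS", "tyrRS", "trpRS", "metRS"})
CLASS_II = frozenset({"serRS", "thrRS", "proRS", "hisRS", "aspRS", "asnRS",
                      "lysRS", "alaRS", "glyRS", "pheRS"})


def canonical_variant(name: str) -> tuple[str, bool]:
    """(scheme variant, tRNA_required flag) for one of the 20 E. coli AARSs.

    Class II enzymes and the class I dimer metRS use the flip-flop scheme;
    argRS/gluRS/glnRS require tRNA for activation; all other class I
    enzymes (including the half-of-sites dimers tyrRS and trpRS) use the
    monomer scheme.
    """
    if name in TRNA_REQUIRED_ENZYMES:
        return CLASS1_TRNA_REQUIRED, True
    if name == "metRS" or name in CLASS_II:
        return CLASS2_FLIPFLOP, False
    if name in CLASS_I:
        return CLASS1_MONOMER, False
    raise SchemeError(f"unknown enzyme {name!r}")


@dataclass
class EnzymeModel:
    """A named enzyme: scheme variant + rate constants + class metadata."""

    name: str
    klass: str                   # "I" or "II"
    variant: str
    rates: RateSet
    sites: int = 1
    trna_required: bool = False
    scheme: ReactionScheme = field(default=None, repr=False)

    def __post_init__(self):
        if self.scheme is None:
            self.scheme = build_scheme(self.variant, self.trna_required)
        if self.klass not in ("I", "II"):
            raise SchemeError("enzyme class must be 'I' or 'II'")
        if self.name in CLASS_I | CLASS_II:
            want_variant, want_flag = canonical_variant(self.name)
            if (self.variant, self.trna_required) != (want_variant, want_flag):
                raise SchemeError(
                    f"{self.name} must use variant {want_variant} "
                    f"(tRNA_required={want_flag})")
        missing = {st.id for st in self.scheme.steps} - set(self.rates)
        if missing:
            raise SchemeError(f"rate set missing steps: {sorted(missing)}")


# ---------------------------------------------------------------------------
# scheme construction
# ---------------------------------------------------------------------------

def _st(label: str, *sites: Iterable) -> EnzymeState:
    return EnzymeState(label, tuple(frozenset(s) for s in sites))


def _class1_states() -> tuple[EnzymeState, ...]:
    return (
        _st("S0", ()),                  # E
        _st("S1", ("A",)),              # E.A
        _st("S2", ("T",)),              # E.T
        _st("S3", ("A", "T")),          # E.A.T
        _st("S4", ("D", "P")),          # E.D.P (adenylate + PPi)
        _st("S5", ("D",)),              # E.D
        _st("S6", ("R",)),              # E.R
        _st("S7", ("A", "R")),
        _st("S8", ("T", "R")),
        _st("S9", ("A", "T", "R")),
        _st("S10", ("D", "P", "R")),
        _st("S11", ("D", "R")),
        _st("S12", ("M", "P", "R*")),   # post-transfer, PPi still bound
        _st("S13", ("M", "R*")),
        _st("S14", ("R*",)),
        _st("S15", ("T", "R*")),        # ATP binds before product release
    )


def _class1_steps(trna_required: bool) -> tuple[ReactionStep, ...]:
    R = ReactionStep
    steps = [
        # random binding of amino acid and ATP to the free enzyme
        R("aa_bind", "S0", "S1", "binding", consumes=AA),
        R("atp_bind", "S0", "S2", "binding", consumes=ATP),
        R("atp_bind_a", "S1", "S3", "binding", consumes=ATP),
        R("aa_bind_t", "S2", "S3", "binding", consumes=AA),
        # activation without tRNA (absent for argRS/gluRS/glnRS)
        R("act", "S3", "S4", "activation"),
        R("ppi_rel", "S4", "S5", "release", releases=PPI),
        # tRNA binds any tRNA-free state except the transient S4
        R("trna_bind_0", "S0", "S6", "binding", consumes=TRNA),
        R("trna_bind_a", "S1", "S7", "binding", consumes=TRNA),
        R("trna_bind_t", "S2", "S8", "binding", consumes=TRNA),
        R("trna_bind_at", "S3", "S9", "binding", consumes=TRNA),
        R("trna_bind_d", "S5", "S11", "binding", consumes=TRNA),
        # random binding with tRNA on board
        R("aa_bind_r", "S6", "S7", "binding", consumes=AA),
        R("atp_bind_r", "S6", "S8", "binding", consumes=ATP),
        R("atp_bind_ra", "S7", "S9", "binding", consumes=ATP),
        R("aa_bind_rt", "S8", "S9", "binding", consumes=AA),
        # activation with tRNA bound
        R("act_r", "S9", "S10", "activation"),
        # PPi release before transfer ...
        R("ppi_rel_r", "S10", "S11", "release", releases=PPI),
        R("tran", "S11", "S13", "transfer"),
        # ... or transfer before PPi release
        R("tran_p", "S10", "S12", "transfer"),
        R("ppi_rel_q", "S12", "S13", "release", releases=PPI),
        # product release path
        R("amp_rel", "S13", "S14", "release", releases=AMP),
        R("atp_bind_p", "S14", "S15", "binding", consumes=ATP),
        R("prod_rel_t", "S15", "S2", "release", releases=AATRNA),
        R("prod_rel", "S14", "S0", "release", releases=AATRNA),
    ]
    if trna_required:
        steps = [s for s in steps if s.id != "act"]
    return tuple(steps)


def _flipflop_scheme() -> ReactionScheme:
    # site-1 chemistry is the class I path; drop the monomer release tail
    drop = {"atp_bind_p", "prod_rel_t", "prod_rel"}
    base = [s for s in _class1_steps(trna_required=False) if s.id not in drop]
    # widen class I states to two sites (site 2 empty)
    states = [
        EnzymeState(s.label, (s.composition[0], frozenset()))
        for s in _class1_states() if s.label != "S15"
    ]
    states += [
        _st("S15", ("R*",), ("A",)),        # ER*/A
        _st("S16", ("R*",), ("T",)),
        _st("S17", ("R*",), ("A", "T")),
        _st("S18", ("R*",), ("D", "P")),
        _st("S19", ("R*",), ("D",)),
    ]
    R = ReactionStep
    site2 = [
        R("aa_bind_2", "S14", "S15", "binding", consumes=AA, site=1),
        R("atp_bind_2", "S14", "S16", "binding", consumes=ATP, site=1),
        R("atp_bind_2a", "S15", "S17", "binding", consumes=ATP, site=1),
        R("aa_bind_2t", "S16", "S17", "binding", consumes=AA, site=1),
        R("act_2", "S17", "S18", "activation", site=1),
        R("ppi_rel_2", "S18", "S19", "release", releases=PPI, site=1),
        # site-1 product release after site-2 activation; the dimer "flips"
        # so the remaining adenylate site becomes the new site 1
        R("prod_rel_dp", "S18", "S4", "release", releases=AATRNA),
        R("prod_rel_d", "S19", "S5", "release", releases=AATRNA),
    ]
    return ReactionScheme(
        variant=CLASS2_FLIPFLOP,
        states=tuple(states),
        steps=tuple(base + site2),
        product_steps=("tran", "tran_p"),
        exchange_steps=("act", "act_r", "act_2"),
    )


def build_scheme(variant: str, trna_required: bool = False) -> ReactionScheme:
    """Construct and validate a reaction scheme.

    ``trna_required`` may only be combined with the class I variants (it is
    defined only for argRS/gluRS/glnRS).
    """
    if variant not in _VARIANTS:
        raise SchemeError(f"unknown scheme variant {variant!r}")
    if trna_required and variant not in (CLASS1_MONOMER, CLASS1_TRNA_REQUIRED):
        raise SchemeError("tRNA-required activation is defined only for class I schemes")
    if variant == CLASS1_TRNA_REQUIRED and not trna_required:
        trna_required = True

    if variant in (CLASS1_MONOMER, CLASS1_TRNA_REQUIRED):
        scheme = ReactionScheme(
            variant=CLASS1_TRNA_REQUIRED if trna_required else CLASS1_MONOMER,
            states=_class1_states(),
            steps=_class1_steps(trna_required),
            product_steps=("tran", "tran_p"),
            exchange_steps=("act_r",) if trna_required else ("act", "act_r"),
        )
    elif variant == CLASS2_FLIPFLOP:
        scheme = _flipflop_scheme()
    elif variant == PP_EXCHANGE:
        scheme = build_pp_exchange_scheme()
    else:
        scheme = build_single_turnover_scheme()
    scheme.validate()
    return scheme


def build_pp_exchange_scheme() -> ReactionScheme:
    """The 6-state, 12-parameter pyrophosphate-exchange subscheme.

    This is the class I scheme restricted to its tRNA-free states
    S0 (E), S1 (E.A), S2 (E.T), S3 (E.A.T), S4 (E.D.P), S5 (E.D).  The
    exchange observable is the backward firing of the activation step
    (adenylate + PPi -> ATP + amino acid on the enzyme).
    """
    keep = {"S0", "S1", "S2", "S3", "S4", "S5"}
    states = tuple(s for s in _class1_states() if s.label in keep)
    steps = tuple(s for s in _class1_steps(trna_required=False)
                  if s.from_state in keep and s.to_state in keep)
    scheme = ReactionScheme(
        variant=PP_EXCHANGE,
        states=states,
        steps=steps,
        exchange_steps=("act",),
    )
    scheme.validate()
    return scheme


def build_single_turnover_scheme() -> ReactionScheme:
    """The 8-parameter single-turnover (transfer) subscheme.

    Starts from the adenylate-bound enzyme S5: tRNA binding, transfer,
    AMP release and aa-tRNA release.  This is the class I scheme induced
    on {S0, S5, S11, S13, S14}.
    """
    keep = {"S0", "S5", "S11", "S13", "S14"}
    states = tuple(s for s in _class1_states() if s.label in keep)
    steps = tuple(s for s in _class1_steps(trna_required=False)
                  if s.from_state in keep and s.to_state in keep)
    scheme = ReactionScheme(
        variant=SINGLE_TURNOVER,
        states=states,
        steps=steps,
        start_label="S5",
        product_steps=("tran",),
    )
    scheme.validate()
    return scheme
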