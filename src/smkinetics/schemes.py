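"""Continuous-time Markov kinetic schemes for conformational/binding dynamics.

A :class:`KineticScheme` couples a set of named states (each with a relative
conductance level) to a generator matrix ``Q`` (s^-1).  Transitions may carry
Arrhenius parameters ``(A, Ea)`` so rates become temperature dependent, and/or
be flagged pseudo-first-order in a ligand species so the effective rate is
``k * C`` at ligand concentration ``C`` (mol/L).

Conventions
-----------
* ``Q[i, j] >= 0`` for ``i != j``; the diagonal is always recomputed as the
  negative row sum, so callers only need to supply off-diagonal rates.
* When Arrhenius parameters are attached to a transition, the stored ``Q``
  entry is the rate at the reference temperature ``T_REF`` (310.15 K) and
  must equal ``A * exp(-Ea / (R * T_REF))``.
* More folded / more bound states sit at *lower* current levels (positive
  surface charge enrichment gates a p-type nanowire down).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .units import R, T_REF, parse_concentration


@dataclass(frozen=True)
class KineticState:
    """One kinetic state: a name, a relative conductance level, a free-text meaning."""

    name: str
    current_level: float
    meaning: str = ""

    def __post_init__(self):
        if not self.current_level > 0:
            raise ValueError(f"current_level must be > 0, got {self.current_level}")


def arrhenius_prefactor(k_ref: float, ea: float, t_ref: float = T_REF) -> float:
    """Prefactor A such that ``A * exp(-ea / (R * t_ref)) == k_ref``."""
    return k_ref * math.exp(ea / (R * t_ref))


@dataclass
class KineticScheme:
    """States plus generator matrix, with optional Arrhenius / ligand dressing.

    Parameters
    ----------
    states:
        Ordered list of :class:`KineticState`; state indices refer to this order.
    Q:
        (n, n) rate matrix in s^-1 (pseudo-first-order entries in 1/(M s));
        off-diagonals >= 0. The diagonal is recomputed on construction.
    arrhenius:
        Map ``(i, j) -> (A, Ea)`` with A in s^-1 and Ea in J/mol.
    pseudo_first_order:
        Map ``(i, j) -> species name``; the effective rate at concentration
        ``C`` of that species is ``Q[i, j] * C``.
    """

    states: list[KineticState]
    Q: np.ndarray
    arrhenius: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    pseudo_first_order: dict[tuple[int, int], str] = field(default_factory=dict)
    scheme_id: str = ""

    def __post_init__(self):
        names = [s.name for s in self.states]
        if len(set(names)) != len(names):
            raise ValueError(f"state names must be unique, got {names}")
        Q = np.array(self.Q, dtype=float)
        n = len(self.states)
        if Q.shape != (n, n):
            raise ValueError(f"Q must be ({n}, {n}), got {Q.shape}")
        off = Q[~np.eye(n, dtype=bool)]
        if np.any(off < 0) or not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal rates must be finite and >= 0")
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        self.Q = Q
        for (i, j), (A, ea) in self.arrhenius.items():
            k_ref = A * math.exp(-ea / (R * T_REF))
            if not math.isclose(Q[i, j], k_ref, rel_tol=1e-6, abs_tol=1e-12):
                raise ValueError(
                    f"Q[{i},{j}]={Q[i, j]:g} inconsistent with Arrhenius rate "
                    f"A*exp(-Ea/(R*T_ref))={k_ref:g} at T_ref={T_REF} K"
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def levels(self) -> np.ndarray:
        return np.array([s.current_level for s in self.states])

    def state_index(self, name: str) -> int:
        for i, s in enumerate(self.states):
            if s.name == name:
                return i
        raise KeyError(f"no state named {name!r}")

    @classmethod
    def from_rates(
        cls,
        states: list[KineticState],
        rates: dict[tuple[int, int], float],
        **kwargs,
    ) -> "KineticScheme":
        n = len(states)
        Q = np.zeros((n, n))
        for (i, j), k in rates.items():
            Q[i, j] = k
        return cls(states=states, Q=Q, **kwargs)

    def effective_rate_matrix(
        self,
        T: float | None = None,
        concentrations: dict[str, float] | None = None,
    ) -> np.ndarray:
        """Generator at temperature ``T`` (K) and the given ligand concentrations.

        Transitions without Arrhenius parameters are temperature independent;
        pseudo-first-order transitions with no concentration given default to
        zero ligand.
        """
        Q = self.Q.copy()
        np.fill_diagonal(Q, 0.0)
        if T is not None:
            if T <= 0:
                raise ValueError(f"temperature must be > 0 K, got {T}")
            for (i, j), (A, ea) in self.arrhenius.items():
                Q[i, j] = A * math.exp(-ea / (R * T))
        conc = {k: parse_concentration(v) for k, v in (concentrations or {}).items()}
        for (i, j), species in self.pseudo_first_order.items():
            Q[i, j] *= conc.get(species, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def with_modified_rates(self, rates: dict[tuple[int, int], float]) -> "KineticScheme":
        Q = self.Q.copy()
        for (i, j), k in rates.items():
            Q[i, j] = k
        return dataclasses.replace(self, Q=Q)


def rates_at_temperature(scheme: KineticScheme, T: float) -> np.ndarray:
    """Rate matrix at temperature ``T`` (K): ``k(T) = A exp(-Ea/(R T))`` for
    Arrhenius-dressed transitions, other entries unchanged."""
    if T <= 0:
        raise ValueError(f"temperature must be > 0 K, got {T}")
    return scheme.effective_rate_matrix(T=T, concentrations=None) if not scheme.pseudo_first_order else _rates_at_temperature_keep_pfo(scheme, T)


def _rates_at_temperature_keep_pfo(scheme: KineticScheme, T: float) -> np.ndarray:
    # Temperature dressing only; pseudo-first-order entries kept as second-order constants.
    Q = scheme.Q.copy()
    np.fill_diagonal(Q, 0.0)
    for (i, j), (A, ea) in scheme.arrhenius.items():
        Q[i, j] = A * math.exp(-ea / (R * T))
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _communicating_classes(Q: np.ndarray) -> list[set[int]]:
    n = Q.shape[0]
    adj = (Q > 0) & ~np.eye(n, dtype=bool)
    reach = adj | np.eye(n, dtype=bool)
    for _ in range(n):  # boolean transitive closure
        new = reach | (reach @ reach)
        if np.array_equal(new, reach):
            break
        reach = new
    seen: set[int] = set()
    classes = []
    for i in range(n):
        if i in seen:
            continue
        cls = {j for j in range(n) if reach[i, j] and reach[j, i]}
        classes.append(cls)
        seen |= cls
    return [c for c in classes]


def stationary_distribution(
    scheme: KineticScheme | np.ndarray,
    T: float | None = None,
    concentrations: dict[str, float] | None = None,
) -> np.ndarray:
    """Stationary occupancy vector pi with ``pi @ Q = 0`` and ``sum(pi) = 1``.

    The chain must have a single closed communicating class; transient states
    (reachable-from but not returning) receive zero mass.  Two or more closed
    classes make the stationary law ambiguous and raise a ``ValueError``
    naming the disconnected states.
    """
    if isinstance(scheme, KineticScheme):
        Q = scheme.effective_rate_matrix(T=T, concentrations=concentrations)
        names = [s.name for s in scheme.states]
    else:
        Q = np.array(scheme, dtype=float)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        names = [str(i) for i in range(Q.shape[0])]
    n = Q.shape[0]
    classes = _communicating_classes(Q)
    closed = []
    for cls in classes:
        outside = [j for j in range(n) if j not in cls]
        if not outside or not np.any(Q[np.ix_(sorted(cls), outside)] > 0):
            closed.append(cls)
    if len(closed) != 1:
        detail = "; ".join("{" + ", ".join(names[i] for i in sorted(c)) + "}" for c in closed)
        raise ValueError(
            f"chain is reducible with {len(closed)} closed classes ({detail}); "
            "stationary distribution is not unique"
        )
    idx = sorted(closed[0])
    Qc = Q[np.ix_(idx, idx)]
    np.fill_diagonal(Qc, 0.0)
    np.fill_diagonal(Qc, -Qc.sum(axis=1))
    m = len(idx)
    A = np.vstack([Qc.T, np.ones(m)])
    b = np.zeros(m + 1)
    b[-1] = 1.0
    pi_c, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi_c = np.clip(pi_c, 0.0, None)
    pi_c /= pi_c.sum()
    pi = np.zeros(n)
    pi[idx] = pi_c
    return pi


# ---------------------------------------------------------------------------
# Scheme builders for the systems under study
# ---------------------------------------------------------------------------

#: Default relative-conductance drop per partial-folding step.
FOLD_STEP = 0.03
#: Default relative-conductance drop of the fully bound complex below the
#: encounter intermediate.
BOUND_STEP = 0.06


def build_binding_scheme(
    kd: float,
    k_off: float = 200.0,
    partner: str = "partner",
    unbound_level: float = 1.0 - FOLD_STEP,
    bound_level: float = 1.0 - FOLD_STEP - BOUND_STEP,
    arrhenius: dict[str, tuple[float, float]] | None = None,
) -> KineticScheme:
    """Two-state bistate binding scheme: encounter intermediate <-> bound complex.

    ``k_on = k_off / kd`` (1/(M s)) is pseudo-first-order in ``partner``; at
    ligand concentration C the stationary bound fraction is ``C / (C + kd)``.

    ``arrhenius`` optionally maps ``"bind"``/``"diss"`` to either an
    activation energy Ea (J/mol; the prefactor is derived so the reference
    rate holds at 310.15 K) or an explicit ``(A, Ea)`` pair.
    """
    kd = parse_concentration(kd)
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if k_off <= 0:
        raise ValueError("k_off must be > 0 (irreversible trap)")
    k_on = k_off / kd
    states = [
        KineticState("Myc*", unbound_level, "encounter intermediate ensemble"),
        KineticState("bound", bound_level, "fully folded binding complex"),
    ]
    arr = {}
    for key, (i, j), k_ref in (("bind", (0, 1), k_on), ("diss", (1, 0), k_off)):
        if arrhenius and key in arrhenius:
            spec = arrhenius[key]
            if isinstance(spec, (int, float)):
                arr[(i, j)] = (arrhenius_prefactor(k_ref, float(spec)), float(spec))
            else:
                arr[(i, j)] = (float(spec[0]), float(spec[1]))
    return KineticScheme.from_rates(
        states,
        {(0, 1): k_on, (1, 0): k_off},
        pseudo_first_order={(0, 1): partner},
        arrhenius=arr,
        scheme_id="binding",
    )


def build_apo_scheme(
    k_01: float = 300.0,
    k_10: float = 7000.0,
    k_12: float = 3000.0,
    k_21: float = 5000.0,
    k_0s: float = 150.0,
    k_s0: float = 2000.0,
) -> KineticScheme:
    """Apo self-folding scheme: linear 0 <-> 1 <-> 2 chain plus a parallel 1*
    branch off the disordered state, with 1 and 1* sharing the medium level.

    Defaults put the medium-state dwells on the hundred-microsecond scale
    (state 1: 1/(k_10 + k_12) = 100 us; state 1*: 1/k_s0 = 500 us) with long
    interludes in the disordered top level between clustered pulses.
    """
    states = [
        KineticState("0", 1.0, "disordered ensemble (highest current)"),
        KineticState("1", 1.0 - FOLD_STEP, "partially folded intermediate"),
        KineticState("2", 1.0 - 2 * FOLD_STEP, "more folded intermediate (lowest current)"),
        KineticState("1*", 1.0 - FOLD_STEP, "parallel medium-level intermediate, slower kinetics"),
    ]
    rates = {
        (0, 1): k_01,
        (1, 0): k_10,
        (1, 2): k_12,
        (2, 1): k_21,
        (0, 3): k_0s,
        (3, 0): k_s0,
    }
    return KineticScheme.from_rates(states, rates, scheme_id="apo")


def build_competition_scheme(
    kd_partner: float,
    kd_inhibitor: float,
    k_off_partner: float = 200.0,
    k_off_inhibitor: float = 500.0,
    topology: str = "distinct",
    k_escape: float = 1000.0,
    fold_ratio: float = 4.0,
    concentrations: dict[str, float] | None = None,
) -> KineticScheme:
    """Mutually exclusive partner/inhibitor binding to the same molecule.

    topology="shared"
        Purely competitive three-state star: one unbound state, association
        to either ligand pseudo-first-order.  Stationary partner occupancy
        follows the Cheng-Prusoff form with apparent
        ``K_D = kd_partner * (1 + [I] / kd_inhibitor)``.
    topology="distinct" (default)
        Each ligand is reached through its own encounter-intermediate state
        (Myc* for the partner, Myc*i for the inhibitor) branching off the
        disordered free state.  Branch rates are calibrated so each branch
        alone half-saturates at its ``kd``.

    ``concentrations`` is validated (>= 0) but not baked in; ligand
    concentrations are supplied when simulating or solving the scheme.
    """
    kd_p = parse_concentration(kd_partner)
    kd_i = parse_concentration(kd_inhibitor)
    if kd_p <= 0 or kd_i <= 0:
        raise ValueError("both dissociation constants must be > 0")
    if k_off_partner <= 0 or k_off_inhibitor <= 0:
        raise ValueError("zero dissociation rate with nonzero association is an irreversible trap")
    for name, c in (concentrations or {}).items():
        if parse_concentration(c) < 0:
            raise ValueError(f"concentration of {name} must be >= 0")

    if topology == "shared":
        states = [
            KineticState("Myc*", 1.0 - FOLD_STEP, "shared encounter intermediate"),
            KineticState("bound_partner", 1.0 - FOLD_STEP - BOUND_STEP, "partner-bound complex"),
            KineticState("bound_inhibitor", 1.0 - FOLD_STEP - BOUND_STEP / 2, "inhibitor-bound complex"),
        ]
        rates = {
            (0, 1): k_off_partner / kd_p,
            (1, 0): k_off_partner,
            (0, 2): k_off_inhibitor / kd_i,
            (2, 0): k_off_inhibitor,
        }
        return KineticScheme.from_rates(
            states,
            rates,
            pseudo_first_order={(0, 1): "partner", (0, 2): "inhibitor"},
            scheme_id="competition_shared",
        )
    if topology == "distinct":
        # Branch: F -(k_enc*C)-> E -(k_fold)-> B with E->F = k_escape,
        # B->E = k_off.  Bound fraction = a*b*C / (1 + a*C + a*b*C) with
        # a = k_enc/k_escape, b = k_fold/k_off; half-saturation at
        # C50 = 1/(a*(1+b)), so a = 1/(kd*(1+b)).
        b_p = fold_ratio
        b_i = fold_ratio
        a_p = 1.0 / (kd_p * (1.0 + b_p))
        a_i = 1.0 / (kd_i * (1.0 + b_i))
        states = [
            KineticState("free", 1.0, "disordered free ensemble"),
            KineticState("Myc*", 1.0 - FOLD_STEP, "partner encounter intermediate"),
            KineticState("bound_partner", 1.0 - FOLD_STEP - BOUND_STEP, "partner-bound complex"),
            KineticState("Myc*i", 1.0 - FOLD_STEP / 2, "inhibitor encounter intermediate"),
            KineticState("bound_inhibitor", 1.0 - FOLD_STEP - BOUND_STEP / 2, "inhibitor-bound complex"),
        ]
        rates = {
            (0, 1): a_p * k_escape,
            (1, 0): k_escape,
            (1, 2): b_p * k_off_partner,
            (2, 1): k_off_partner,
            (0, 3): a_i * k_escape,
            (3, 0): k_escape,
            (3, 4): b_i * k_off_inhibitor,
            (4, 3): k_off_inhibitor,
        }
        return KineticScheme.from_rates(
            states,
            rates,
            pseudo_first_order={(0, 1): "partner", (0, 3): "inhibitor"},
            scheme_id="competition_distinct",
        )
    raise ValueError(f"unknown topology {topology!r} (use 'shared' or 'distinct')")
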