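"""Continuous-time Markov simulation of channel gating plus open-channel block.

States are labelled (Closed, Open, OpenBlocked, ...), transitions carry
:class:`RateLaw` objects whose numeric value depends on the protocol segment
(ligand concentrations, membrane voltage).  The master equation
dp/dt = p Q is propagated exactly per piecewise-constant segment with the
matrix exponential.

Gate-blocker interaction modes
------------------------------
trapping
    The activation gate can close over the bound blocker
    (OpenBlocked <-> ClosedBlocked); the trapped molecule cannot leave
    until the channel reopens.
foot_in_door
    The bound blocker props the gate open: there is no
    OpenBlocked -> ClosedBlocked transition, so blocked channels must
    transit the open state to close, producing tail currents on washout.
permeant
    As foot_in_door, plus an escape path OpenBlocked -> Open in which the
    blocker is swept through the channel into the cytoplasm at negative
    voltages.  Under concentration clamp the lost molecule is replaced
    from the bath, which keeps the chain irreducible.
allosteric
    Adds an independent voltage-insensitive site, modelled as an
    instantaneous-equilibrium factor 1/(1 + C/K_vin) scaling open-state
    conductance (the fast-kinetics limit).

Rate constants are not constrained by the steady-state block models; the
mapping used here puts the voltage dependence entirely on unbinding and
permeation (binding voltage-independent):

    k_on   = kon_per_uM * C
    k_off  = kon_per_uM * K_b * exp(+z delta_b V / Vt)
    k_perm = kon_per_uM * K_p * exp(-z delta_p V / Vt)

so the open-state balance reproduces the closed-form effective K_d exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.optimize import curve_fit
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .models import BlockParams, IlluminationState, DARK, ThermoContext

__all__ = [
    "RateLaw",
    "Transition",
    "AllostericSite",
    "KineticScheme",
    "Segment",
    "Protocol",
    "TimeCourse",
    "GatingRates",
    "BlockRates",
    "SchemeError",
    "ReducibleSchemeError",
    "build_block_scheme",
    "build_competition_scheme",
    "simulate",
    "steady_state",
    "unblocked_fraction",
    "detailed_balance_violation",
    "tail_current_index",
    "double_pulse_residual",
    "competition_recovery_tau",
    "standard_competition_protocol",
    "slow_trapping_reference",
]


class SchemeError(ValueError):
    """Scheme construction or configuration problem."""


class ReducibleSchemeError(RuntimeError):
    """Rate matrix is reducible under the given conditions."""

    def __init__(self, message: str, closed_classes: list[list[str]]):
        super().__init__(message)
        self.closed_classes = closed_classes


@dataclass(frozen=True)
class RateLaw:
    """Rate = base_rate * [ligand] * exp(sign * z * delta * V / Vt).

    ``base_rate`` is per second, or per second per uM when ``ligand`` is
    set (bimolecular step scaled by the segment concentration of that
    ligand: ``"agonist"`` or a blocker name).  ``voltage_sign`` in
    {-1, 0, +1} selects the direction of voltage dependence; ``delta`` is
    the electrical depth and ``z`` the moving charge.
    """

    base_rate: float
    ligand: str | None = None
    voltage_sign: int = 0
    delta: float = 0.0
    z: int = 1

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise SchemeError(f"base_rate must be >= 0, got {self.base_rate}")
        if self.voltage_sign not in (-1, 0, 1):
            raise SchemeError(f"voltage_sign must be -1, 0 or +1, got {self.voltage_sign}")
        if not 0.0 <= self.delta <= 1.0:
            raise SchemeError(f"delta must lie in [0, 1], got {self.delta}")

    def value(self, segment: "Segment", thermo: ThermoContext) -> float:
        rate = self.base_rate
        if self.ligand is not None:
            if self.ligand == "agonist":
                rate *= segment.agonist
            else:
                rate *= segment.blockers.get(self.ligand, 0.0)
        if self.voltage_sign != 0:
            rate *= np.exp(
                self.voltage_sign * self.z * self.delta * segment.voltage / thermo.vt_mV
            )
        if not np.isfinite(rate):
            raise FloatingPointError(
                f"non-finite rate from {self!r} at V={segment.voltage} mV"
            )
        return rate


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    rate: RateLaw
    #: blocker leaves to the cytoplasm on this step (permeation); under
    #: concentration clamp the scheme topology is unchanged, but the edge
    #: is excluded from microscopic-reversibility bookkeeping.
    permeation: bool = False


@dataclass(frozen=True)
class AllostericSite:
    """Independent voltage-insensitive site scaling open-state conductance."""

    ligand: str
    K: float

    def factor(self, segment: "Segment") -> float:
        C = segment.blockers.get(self.ligand, 0.0)
        return 1.0 / (1.0 + C / self.K)


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant epoch of an experimental protocol."""

    duration: float
    voltage: float = -70.0
    agonist: float = 0.0
    blockers: dict = field(default_factory=dict)
    illumination: IlluminationState = DARK

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise SchemeError(f"segment duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class Protocol:
    segments: tuple[Segment, ...]

    def __init__(self, segments) -> None:
        object.__setattr__(self, "segments", tuple(segments))
        if not self.segments:
            raise SchemeError("protocol needs at least one segment")

    @property
    def total_duration(self) -> float:
        return sum(s.duration for s in self.segments)


@dataclass(frozen=True)
class KineticScheme:
    """Labelled states, transitions, and relative conductances."""

    states: tuple[str, ...]
    transitions: tuple[Transition, ...]
    conductance: dict
    allosteric: AllostericSite | None = None
    #: conducting states and their blocked counterparts, used by
    #: :func:`unblocked_fraction`
    open_states: tuple[str, ...] = ()
    open_blocked_states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        index = {s: i for i, s in enumerate(self.states)}
        if len(index) != len(self.states):
            raise SchemeError("duplicate state labels")
        for t in self.transitions:
            for s in (t.source, t.target):
                if s not in index:
                    raise SchemeError(f"transition references unknown state {s!r}")
            if t.source == t.target:
                raise SchemeError(f"self-loop on state {t.source!r}")
        for s, g in self.conductance.items():
            if s not in index:
                raise SchemeError(f"conductance for unknown state {s!r}")
            if not 0.0 <= g <= 1.0:
                raise SchemeError(f"conductance must lie in [0, 1], got {g} for {s!r}")

    def state_index(self, label: str) -> int:
        return self.states.index(label)

    def has_transition(self, source: str, target: str) -> bool:
        return any(t.source == source and t.target == target for t in self.transitions)

    def rate_matrix(self, segment: Segment, thermo: ThermoContext = ThermoContext()) -> np.ndarray:
        """Generator matrix Q (rows sum to zero; Q[i, j] = rate i -> j)."""
        n = len(self.states)
        index = {s: i for i, s in enumerate(self.states)}
        Q = np.zeros((n, n))
        for t in self.transitions:
            Q[index[t.source], index[t.target]] += t.rate.value(segment, thermo)
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q

    def conductance_vector(self) -> np.ndarray:
        return np.array([self.conductance.get(s, 0.0) for s in self.states])

    def current(self, occupancy: np.ndarray, segment: Segment, e_rev: float = 0.0) -> np.ndarray:
        """Macroscopic current, arbitrary units; inward (V < E_rev) is negative."""
        g = occupancy @ self.conductance_vector()
        if self.allosteric is not None:
            g = g * self.allosteric.factor(segment)
        return g * (segment.voltage - e_rev)


@dataclass(frozen=True)
class GatingRates:
    """Two-state gating: opening scaled by agonist concentration."""

    opening_per_uM: float = 0.5   # /s/uM of agonist
    closing: float = 25.0         # /s


@dataclass(frozen=True)
class BlockRates:
    """Bimolecular association rate of the blocker with the open pore."""

    kon_per_uM: float = 0.7       # /s/uM


def slow_trapping_reference(
    thermo: ThermoContext = ThermoContext(),
) -> tuple[BlockParams, BlockRates]:
    """Slow, high-affinity trapping pore blocker (adamantane-derivative-like).

    Effective K_d of 0.5 uM at the −70 mV working potential (delta_b = 0.7,
    z = 2) with slow binding kinetics (k_on 0.25 /s/uM, hence k_off
    0.125 /s at −70 mV) — recovery time constants of tens of seconds, the
    regime in which the trapped blocker survives agonist washout.
    """
    kd_at_m70 = 0.5
    K_b = kd_at_m70 * np.exp(-2 * 0.7 * (-70.0) / thermo.vt_mV)
    return BlockParams(K_b=K_b, delta_b=0.7, z=2), BlockRates(kon_per_uM=0.25)


@dataclass(frozen=True)
class TimeCourse:
    time: np.ndarray
    occupancy: np.ndarray          # shape (T, n_states)
    states: tuple[str, ...]
    current: np.ndarray
    segment_index: np.ndarray

    def occupancy_of(self, state: str) -> np.ndarray:
        return self.occupancy[:, self.states.index(state)]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "time_s", self.time)
        df["current"] = self.current
        df["segment"] = self.segment_index
        return df


_MODES = ("trapping", "foot_in_door", "permeant", "allosteric")


def build_block_scheme(
    mode: str,
    gating: GatingRates,
    block: BlockRates,
    params: BlockParams,
    thermo: ThermoContext = ThermoContext(),
    blocker: str = "blocker",
) -> KineticScheme:
    """Assemble a gating-plus-block scheme in the requested interaction mode.

    The blocked-state rates are mapped from the steady-state parameters so
    that the open-state occupancy balance reproduces the closed-form
    effective K_d (see module docstring).  ``permeant`` requires K_p > 0;
    ``allosteric`` requires a finite K_vin and builds on the permeant
    scheme when K_p > 0.
    """
    if mode not in _MODES:
        raise SchemeError(f"unknown mode {mode!r}; expected one of {_MODES}")
    if mode == "permeant" and params.K_p <= 0:
        raise SchemeError("permeant mode requires K_p > 0")
    if mode == "allosteric" and params.K_vin is None:
        raise SchemeError("allosteric mode requires a finite K_vin")

    states = ["Closed", "Open", "OpenBlocked"]
    transitions = [
        Transition("Closed", "Open", RateLaw(gating.opening_per_uM, ligand="agonist")),
        Transition("Open", "Closed", RateLaw(gating.closing)),
        Transition("Open", "OpenBlocked", RateLaw(block.kon_per_uM, ligand=blocker)),
        Transition(
            "OpenBlocked",
            "Open",
            RateLaw(block.kon_per_uM * params.K_b, voltage_sign=+1,
                    delta=params.delta_b, z=params.z),
        ),
    ]
    if params.K_p > 0:
        transitions.append(
            Transition(
                "OpenBlocked",
                "Open",
                RateLaw(block.kon_per_uM * params.K_p, voltage_sign=-1,
                        delta=params.delta_p, z=params.z),
                permeation=True,
            )
        )
    if mode == "trapping":
        states.append("ClosedBlocked")
        transitions += [
            Transition("OpenBlocked", "ClosedBlocked", RateLaw(gating.closing)),
            Transition("ClosedBlocked", "OpenBlocked",
                       RateLaw(gating.opening_per_uM, ligand="agonist")),
        ]
    allosteric = None
    if mode == "allosteric":
        allosteric = AllostericSite(ligand=blocker, K=params.K_vin)
    return KineticScheme(
        states=tuple(states),
        transitions=tuple(transitions),
        conductance={s: (1.0 if s == "Open" else 0.0) for s in states},
        allosteric=allosteric,
        open_states=("Open",),
        open_blocked_states=("OpenBlocked",),
    )


def build_competition_scheme(
    gating: GatingRates,
    slow_params: BlockParams,
    slow_block: BlockRates,
    partner: str = "none",
    partner_params: BlockParams | None = None,
    partner_block: BlockRates | None = None,
    thermo: ThermoContext = ThermoContext(),
    slow_name: str = "slow",
    partner_name: str = "partner",
) -> KineticScheme:
    """Trapping slow pore blocker plus an optional second antagonist.

    partner = "pore": the second blocker competes for the same open-pore
    site (occupancy competition; a site occupied by one molecule is
    unavailable to the other).  partner = "allosteric": an independent
    site scaling conductance, which cannot displace the pore blocker.
    partner = "none": the slow blocker alone.
    """
    if partner not in ("none", "pore", "allosteric"):
        raise SchemeError(f"unknown partner kind {partner!r}")
    states = ["Closed", "Open", "OpenBlockedSlow", "ClosedBlockedSlow"]
    transitions = [
        Transition("Closed", "Open", RateLaw(gating.opening_per_uM, ligand="agonist")),
        Transition("Open", "Closed", RateLaw(gating.closing)),
        Transition("Open", "OpenBlockedSlow", RateLaw(slow_block.kon_per_uM, ligand=slow_name)),
        Transition(
            "OpenBlockedSlow",
            "Open",
            RateLaw(slow_block.kon_per_uM * slow_params.K_b, voltage_sign=+1,
                    delta=slow_params.delta_b, z=slow_params.z),
        ),
        Transition("OpenBlockedSlow", "ClosedBlockedSlow", RateLaw(gating.closing)),
        Transition("ClosedBlockedSlow", "OpenBlockedSlow",
                   RateLaw(gating.opening_per_uM, ligand="agonist")),
    ]
    allosteric = None
    open_blocked = ["OpenBlockedSlow"]
    if partner == "pore":
        if partner_params is None or partner_block is None:
            raise SchemeError("pore partner requires partner_params and partner_block")
        states.append("OpenBlockedFast")
        transitions += [
            Transition("Open", "OpenBlockedFast",
                       RateLaw(partner_block.kon_per_uM, ligand=partner_name)),
            Transition(
                "OpenBlockedFast",
                "Open",
                RateLaw(partner_block.kon_per_uM * partner_params.K_b, voltage_sign=+1,
                        delta=partner_params.delta_b, z=partner_params.z),
            ),
        ]
        if partner_params.K_p > 0:
            transitions.append(
                Transition(
                    "OpenBlockedFast",
                    "Open",
                    RateLaw(partner_block.kon_per_uM * partner_params.K_p,
                            voltage_sign=-1, delta=partner_params.delta_p,
                            z=partner_params.z),
                    permeation=True,
                )
            )
        open_blocked.append("OpenBlockedFast")
    elif partner == "allosteric":
        if partner_params is None or partner_params.K_vin is None:
            raise SchemeError("allosteric partner requires partner_params with K_vin")
        allosteric = AllostericSite(ligand=partner_name, K=partner_params.K_vin)
    return KineticScheme(
        states=tuple(states),
        transitions=tuple(transitions),
        conductance={s: (1.0 if s == "Open" else 0.0) for s in states},
        allosteric=allosteric,
        open_states=("Open",),
        open_blocked_states=tuple(open_blocked),
    )


def simulate(
    scheme: KineticScheme,
    protocol: Protocol,
    dt: float,
    p0: np.ndarray | None = None,
    thermo: ThermoContext = ThermoContext(),
    e_rev: float = 0.0,
) -> TimeCourse:
    """Propagate the master equation over a piecewise-constant protocol.

    Per segment the propagator expm(Q dt) is applied on a uniform grid
    (plus a fractional step to land exactly on the segment boundary), so
    the trajectory is exact for the given scheme up to roundoff and
    deterministic.  Probability conservation is checked to 1e-9.
    """
    if not dt > 0:
        raise SchemeError(f"dt must be > 0, got {dt}")
    if dt > min(s.duration for s in protocol.segments) + 1e-12:
        raise SchemeError("dt must not exceed the shortest protocol segment")
    n = len(scheme.states)
    if p0 is None:
        p = np.zeros(n)
        p[scheme.state_index("Closed")] = 1.0
    else:
        p = np.asarray(p0, dtype=float).copy()
        if p.shape != (n,) or abs(p.sum() - 1.0) > 1e-9 or np.any(p < -1e-12):
            raise SchemeError("p0 must be a probability vector over the states")

    times = [0.0]
    occ = [p.copy()]
    seg_idx = [0]
    t0 = 0.0
    for k, seg in enumerate(protocol.segments):
        Q = scheme.rate_matrix(seg, thermo)
        if not np.all(np.isfinite(Q)):
            raise FloatingPointError(f"non-finite rate matrix in segment {k}")
        P = expm(Q * dt)
        n_full = int(np.floor(seg.duration / dt + 1e-9))
        rem = seg.duration - n_full * dt
        for i in range(n_full):
            p = p @ P
            times.append(t0 + (i + 1) * dt)
            occ.append(p.copy())
            seg_idx.append(k)
        if rem > 1e-12:
            p = p @ expm(Q * rem)
            times.append(t0 + seg.duration)
            occ.append(p.copy())
            seg_idx.append(k)
        t0 += seg.duration
        if abs(p.sum() - 1.0) > 1e-9:
            raise FloatingPointError(
                f"probability not conserved in segment {k}: sum={p.sum()!r}"
            )

    time = np.array(times)
    occupancy = np.vstack(occ)
    seg_idx = np.array(seg_idx)
    current = np.empty(len(time))
    for k, seg in enumerate(protocol.segments):
        m = seg_idx == k
        current[m] = scheme.current(occupancy[m], seg, e_rev)
    return TimeCourse(time=time, occupancy=occupancy, states=scheme.states,
                      current=current, segment_index=seg_idx)


def _closed_classes(Q: np.ndarray, states: tuple[str, ...]) -> list[list[str]]:
    adj = csr_matrix((Q > 0).astype(int))
    n_comp, labels = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.where(labels == c)[0]
        outside = np.setdiff1d(np.arange(len(states)), members)
        if outside.size == 0 or not np.any(Q[np.ix_(members, outside)] > 0):
            closed.append([states[i] for i in members])
    return closed


def steady_state(
    scheme: KineticScheme,
    segment: Segment,
    thermo: ThermoContext = ThermoContext(),
) -> np.ndarray:
    """Stationary occupancy under one set of conditions (null-space solve).

    Requires the rate graph to be irreducible (one strongly connected
    component); otherwise :class:`ReducibleSchemeError` reports the
    absorbing (closed) communicating classes.
    """
    Q = scheme.rate_matrix(segment, thermo)
    adj = csr_matrix((Q > 0).astype(int))
    n_comp, _ = connected_components(adj, directed=True, connection="strong")
    if n_comp > 1:
        closed = _closed_classes(Q, scheme.states)
        raise ReducibleSchemeError(
            f"rate matrix reducible under {segment}; closed classes: {closed}",
            closed_classes=closed,
        )
    n = len(scheme.states)
    A = np.vstack([Q.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.where(np.abs(pi) < 1e-15, 0.0, pi)
    if np.any(pi < -1e-10):
        raise FloatingPointError(f"negative stationary occupancy: {pi}")
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def unblocked_fraction(
    scheme: KineticScheme,
    occupancy: np.ndarray,
    segment: Segment | None = None,
) -> float:
    """Conducting fraction of open-or-open-blocked channels.

    P(open) / (P(open) + P(open-blocked)), times the allosteric
    conductance factor when the scheme carries an independent site.  At
    steady state this equals the closed-form inhibition ratio
    I_drug/I_control of the corresponding block model (the current ratio
    itself converges to the same quantity at saturating agonist).
    """
    occupancy = np.asarray(occupancy, dtype=float)
    po = sum(occupancy[scheme.state_index(s)] for s in scheme.open_states)
    pb = sum(occupancy[scheme.state_index(s)] for s in scheme.open_blocked_states)
    if po + pb <= 0:
        raise ValueError("no open or open-blocked occupancy; fraction undefined")
    frac = po / (po + pb)
    if scheme.allosteric is not None:
        if segment is None:
            raise ValueError("segment required to evaluate the allosteric factor")
        frac *= scheme.allosteric.factor(segment)
    return float(frac)


def detailed_balance_violation(
    scheme: KineticScheme,
    segment: Segment,
    thermo: ThermoContext = ThermoContext(),
) -> float:
    """Max relative net edge flux at steady state (0 = detailed balance).

    Permeation edges recycle the blocker through the bath and are expected
    to break microscopic reversibility; with permeation disabled the
    binding loop should satisfy detailed balance to roundoff.
    """
    pi = steady_state(scheme, segment, thermo)
    index = {s: i for i, s in enumerate(scheme.states)}
    # permeation edges recycle through the bath, not the binding reaction:
    # keep them out of the pairing so their flux shows up as imbalance
    fwd: dict[tuple[int, int], float] = {}
    for t in scheme.transitions:
        if t.permeation:
            continue
        key = (index[t.source], index[t.target])
        fwd[key] = fwd.get(key, 0.0) + t.rate.value(segment, thermo)
    worst = 0.0
    scale = max((pi[i] * r for (i, _), r in fwd.items()), default=1.0)
    for (i, j), rate in fwd.items():
        back = fwd.get((j, i), 0.0)
        net = abs(pi[i] * rate - pi[j] * back)
        worst = max(worst, net / scale if scale > 0 else net)
    return worst


def tail_current_index(tc: TimeCourse, washout_time: float) -> float:
    """Peak post-washout current relative to the pre-washout level.

    max |I| over (washout_time, end] divided by |I| at washout_time^-;
    values > 1 signal a tail current (transient overshoot after removal
    of agonist and blocker), the signature of foot-in-the-door block.
    """
    if not (tc.time[0] < washout_time < tc.time[-1]):
        raise ValueError(
            f"washout_time {washout_time} outside simulated window "
            f"[{tc.time[0]}, {tc.time[-1]}]"
        )
    before = tc.time <= washout_time + 1e-12
    i_pre = np.abs(tc.current[before][-1])
    if i_pre == 0:
        raise ValueError("steady current is zero before washout; index undefined")
    after = tc.time > washout_time + 1e-12
    return float(np.abs(tc.current[after]).max() / i_pre)


def double_pulse_residual(
    scheme: KineticScheme,
    blocker: str = "blocker",
    concentration: float = 30.0,
    agonist: float = 100.0,
    voltage: float = -70.0,
    pulse_s: float = 2.0,
    wash_s: float = 1.5,
    measure_at_s: float = 0.02,
    dt: float = 1e-3,
    thermo: ThermoContext = ThermoContext(),
) -> float:
    """Residual block at the start of a second agonist pulse after washout.

    Protocol: control agonist pulse -> wash -> agonist + blocker pulse ->
    blocker-free wash -> test agonist pulse.  Returns
    1 - I_test / I_control, both sampled ``measure_at_s`` after pulse
    onset.  A trapping scheme retains the blocker across the wash
    (positive residual); a foot-in-the-door scheme releases it (residual
    ~ 0).
    """
    segs = [
        Segment(pulse_s, voltage=voltage, agonist=agonist),
        Segment(wash_s, voltage=voltage),
        Segment(pulse_s, voltage=voltage, agonist=agonist,
                blockers={blocker: concentration}),
        Segment(wash_s, voltage=voltage),
        Segment(pulse_s, voltage=voltage, agonist=agonist),
    ]
    tc = simulate(scheme, Protocol(segs), dt=dt, thermo=thermo)
    t_ctrl = measure_at_s
    t_test = 2 * (pulse_s + wash_s) + measure_at_s
    i_ctrl = np.interp(t_ctrl, tc.time, np.abs(tc.current))
    i_test = np.interp(t_test, tc.time, np.abs(tc.current))
    return float(1.0 - i_test / i_ctrl)


def standard_competition_protocol(
    slow_conc: float,
    partner_conc: float = 0.0,
    agonist: float = 100.0,
    voltage: float = -70.0,
    baseline_s: float = 1.0,
    coapp_s: float = 8.0,
    recovery_s: float = 30.0,
    slow_name: str = "slow",
    partner_name: str = "partner",
) -> Protocol:
    """Continuous-agonist co-application / washout protocol for competition."""
    blockers = {slow_name: slow_conc}
    if partner_conc > 0:
        blockers[partner_name] = partner_conc
    return Protocol([
        Segment(baseline_s, voltage=voltage, agonist=agonist),
        Segment(coapp_s, voltage=voltage, agonist=agonist, blockers=blockers),
        Segment(recovery_s, voltage=voltage, agonist=agonist),
    ])


def _fit_recovery_tau(time: np.ndarray, current: np.ndarray) -> float:
    """Mono-exponential time constant of |current| recovery toward plateau."""
    y = np.abs(current)
    t = time - time[0]
    a0 = y[-1] - y[0]
    if abs(a0) < 1e-12:
        raise RuntimeError("no recovery amplitude to fit")
    # crude tau guess: time to cover 63% of the amplitude
    target = y[0] + 0.632 * a0
    crossing = np.nonzero(y >= target)[0] if a0 > 0 else np.nonzero(y <= target)[0]
    tau0 = t[crossing[0]] if crossing.size else t[-1] / 3

    def model(t, y_inf, amp, tau):
        return y_inf - amp * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=[y[-1], a0, max(tau0, t[1])],
            bounds=([0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"recovery exponential fit did not converge: {exc}") from exc
    return float(popt[2])


def competition_recovery_tau(
    gating: GatingRates,
    slow_params: BlockParams,
    slow_block: BlockRates,
    partner: str = "none",
    partner_params: BlockParams | None = None,
    partner_block: BlockRates | None = None,
    slow_conc: float = 2.0,
    partner_conc: float = 500.0,
    protocol: Protocol | None = None,
    dt: float = 2e-3,
    thermo: ThermoContext = ThermoContext(),
) -> float:
    """Recovery time constant (s) after blocker washout with agonist on.

    Builds the competition scheme for the requested partner kind, runs the
    co-application/washout protocol, and fits a mono-exponential to the
    current in the recovery segment.  A pore-site partner at saturating
    concentration keeps the slow blocker out of the channel and speeds
    recovery; an independent allosteric partner leaves it unchanged.
    """
    scheme = build_competition_scheme(
        gating, slow_params, slow_block,
        partner=partner, partner_params=partner_params, partner_block=partner_block,
        thermo=thermo,
    )
    if protocol is None:
        protocol = standard_competition_protocol(
            slow_conc, partner_conc if partner != "none" else 0.0
        )
    tc = simulate(scheme, protocol, dt=dt, thermo=thermo)
    t_wash = sum(s.duration for s in protocol.segments[:-1])
    m = tc.time >= t_wash
    return _fit_recovery_tau(tc.time[m], tc.current[m])
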