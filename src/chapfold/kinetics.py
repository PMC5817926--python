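"""Five-state kinetic model of a protein domain under piecewise-constant force.

A mechanically stretched polyprotein domain is described by five states:

* ``folded``      — natively folded, mechanically stable
* ``ext_free``    — unfolded and extended under force, chaperone-free
* ``ext_bound``   — extended with a chaperone bound (e.g. DnaJ on the
  exposed consensus sequence)
* ``coll_free``   — mechanically labile, molten-globule-like collapsed state
* ``coll_bound``  — collapsed with a chaperone bound (e.g. DnaK·ADP)

Which transitions are active depends on the force regime.  Under a pulling
force (force pulse) the folded state unfolds at ``k_u``, collapsed states
re-extend at ``k_uc`` (preserving bound/free), and the chaperone exchanges on
the extended conformation.  At force quench (~0 pN) the extended free state
collapses at ``k_c``, the collapsed free state folds at ``k_f0``, and the
chaperone exchanges on both extended and collapsed conformations.  Bound
states never fold, and a bound extended domain must release the chaperone
before it can collapse.

The force protocol is piecewise constant, so propagation uses the exact
matrix exponential per segment; no ODE solver tolerances are involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "STATES",
    "FORCE_REGIME_THRESHOLD_PN",
    "KineticScheme",
    "Segment",
    "ForceProtocol",
    "PopulationState",
    "PopulationTrajectory",
    "rate_matrix",
    "propagate",
    "predict_yield",
    "predict_yield_curve",
    "equilibrium_unbound_fraction",
    "pseudo_first_order_rate",
    "kon_multiplier_from_energy",
]

#: State order used by every array in this module.
STATES: tuple[str, ...] = ("folded", "ext_free", "ext_bound", "coll_free", "coll_bound")
_IDX = {s: i for i, s in enumerate(STATES)}
F, EU, EB, CU, CB = range(5)

#: Forces above this value (pN) follow the force-pulse transition rules,
#: forces at or below it the quench rules.  The experiments only ever use
#: ~0 pN versus >=30 pN, so the exact cut is immaterial.
FORCE_REGIME_THRESHOLD_PN: float = 10.0

SEGMENT_LABELS = ("unfold", "extend", "quench", "test")


class InvalidParameterError(ValueError):
    """A rate, concentration or fraction is outside its physical range."""


@dataclass(frozen=True)
class KineticScheme:
    """Rate constants and chaperone-binding topology of the five-state model.

    Parameters
    ----------
    k_u : float
        Unfolding rate (1/s) folded -> ext_free at the reference pulling
        force (120 pN for ubiquitin/I27, 100 pN for Z1).  No force law is
        applied; the rate is taken as measured at that force.
    k_c : float
        Collapse rate (1/s) ext_free -> coll_free during the quench.
    k_f0 : float
        Folding rate (1/s) coll_free -> folded during the quench.
    k_uc : float
        Re-extension rate (1/s) of collapsed states under pulling force.
        Fast by default (50/s): the collapsed state is mechanically labile,
        so only folded domains produce test-pulse steps.
    k_on_ext, k_on_coll : float
        Chaperone association rates, 1/(M s), to the extended / collapsed
        conformation.
    k_off_ext, k_off_coll : float
        Chaperone dissociation rates, 1/s.
    chaperone_conc : float
        Free chaperone concentration, M.
    fold_competence : float
        Fraction of domains able to reach the folded state at all (emulates
        substrates such as Z1 with a low intrinsic yield).  Applied as a
        partition of domains, not as an extra state.
    kon_force_profile : callable or mapping, optional
        Multiplier on ``k_on_ext`` as a function of pulling force (pN),
        e.g. derived from a dihedral free-energy profile via
        :func:`kon_multiplier_from_energy`.  Applied only in the pulse
        regime; tabulated profiles are linearly interpolated and raise
        outside their range.
    """

    k_u: float
    k_c: float
    k_f0: float
    k_uc: float = 50.0
    k_on_ext: float = 0.0
    k_off_ext: float = 0.0
    k_on_coll: float = 0.0
    k_off_coll: float = 0.0
    chaperone_conc: float = 0.0
    fold_competence: float = 1.0
    kon_force_profile: Callable[[float], float] | Mapping[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("k_u", "k_c", "k_f0", "k_uc", "k_on_ext", "k_off_ext",
                     "k_on_coll", "k_off_coll", "chaperone_conc"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0, got {v}")
        if not 0.0 <= self.fold_competence <= 1.0:
            raise InvalidParameterError(
                f"fold_competence must lie in [0, 1], got {self.fold_competence}")

    @property
    def kd_ext(self) -> float:
        """Dissociation constant k_off_ext / k_on_ext (M); requires k_on_ext > 0."""
        if self.k_on_ext <= 0:
            raise InvalidParameterError("K_d(ext) undefined for k_on_ext = 0")
        return self.k_off_ext / self.k_on_ext

    @property
    def kd_coll(self) -> float:
        """Dissociation constant k_off_coll / k_on_coll (M); requires k_on_coll > 0."""
        if self.k_on_coll <= 0:
            raise InvalidParameterError("K_d(coll) undefined for k_on_coll = 0")
        return self.k_off_coll / self.k_on_coll

    def replace(self, **changes) -> "KineticScheme":
        return _dc_replace(self, **changes)

    def kon_multiplier(self, force_pn: float) -> float:
        """Force-dependent multiplier on k_on_ext (1.0 if no profile set)."""
        prof = self.kon_force_profile
        if prof is None:
            return 1.0
        if callable(prof):
            return float(prof(force_pn))
        forces = np.asarray(sorted(prof), dtype=float)
        mults = np.asarray([prof[f] for f in forces], dtype=float)
        if force_pn < forces[0] or force_pn > forces[-1]:
            raise InvalidParameterError(
                f"force {force_pn} pN outside tabulated kon profile "
                f"[{forces[0]}, {forces[-1]}] pN")
        return float(np.interp(force_pn, forces, mults))


@dataclass(frozen=True)
class Segment:
    """One constant-force segment of a protocol."""

    label: str
    force_pn: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(f"segment label {self.label!r} not in {SEGMENT_LABELS}")
        if not self.duration_s > 0:
            raise ValueError("segment duration must be > 0")
        if self.label == "quench":
            if self.force_pn > FORCE_REGIME_THRESHOLD_PN:
                raise ValueError("quench segments must have force ~0 "
                                 f"(<= {FORCE_REGIME_THRESHOLD_PN} pN)")
        elif self.force_pn <= FORCE_REGIME_THRESHOLD_PN:
            raise ValueError(f"{self.label} segments must have force > "
                             f"{FORCE_REGIME_THRESHOLD_PN} pN")


@dataclass(frozen=True)
class ForceProtocol:
    """Ordered piecewise-constant force segments plus a sampling rate.

    Segment labels must follow the experimental order: any ``unfold``
    segment comes first and any ``test`` segment last.
    """

    segments: tuple[Segment, ...]
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        segs = tuple(Segment(*s) if not isinstance(s, Segment) else s
                     for s in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("protocol must contain at least one segment")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        labels = [s.label for s in segs]
        if "unfold" in labels and labels.index("unfold") != 0:
            raise ValueError("'unfold' segment must come first")
        if "test" in labels and labels[-1] != "test":
            raise ValueError("'test' segment must come last")

    @property
    def total_duration_s(self) -> float:
        return sum(s.duration_s for s in self.segments)

    @property
    def boundaries_s(self) -> np.ndarray:
        """Cumulative segment end times, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration_s for s in self.segments])])

    @classmethod
    def force_quench(cls, *, unfold_force_pn: float = 120.0, unfold_s: float = 5.0,
                     t_ext_s: float = 0.0, extend_force_pn: float | None = None,
                     t_q_s: float = 5.0, test_s: float = 5.0,
                     test_force_pn: float | None = None,
                     sampling_rate_hz: float = 1000.0) -> "ForceProtocol":
        """Standard three-pulse protocol: unfold / (extend) / quench / test."""
        segs = [Segment("unfold", unfold_force_pn, unfold_s)]
        if t_ext_s > 0:
            segs.append(Segment("extend", extend_force_pn if extend_force_pn
                                is not None else unfold_force_pn, t_ext_s))
        segs.append(Segment("quench", 0.0, t_q_s))
        if test_s > 0:
            segs.append(Segment("test", test_force_pn if test_force_pn
                                is not None else unfold_force_pn, test_s))
        return cls(tuple(segs), sampling_rate_hz)


class PopulationState:
    """Probability distribution over the five substrate states."""

    __slots__ = ("fractions",)

    def __init__(self, fractions) -> None:
        arr = np.asarray(fractions, dtype=float)
        if arr.shape != (5,):
            raise ValueError("PopulationState needs 5 fractions")
        if np.any(arr < -1e-12):
            raise ValueError("fractions must be >= 0")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {arr.sum()!r}")
        self.fractions = np.clip(arr, 0.0, None)

    @classmethod
    def pure(cls, state: str) -> "PopulationState":
        v = np.zeros(5)
        v[_IDX[state]] = 1.0
        return cls(v)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "PopulationState":
        v = np.zeros(5)
        for k, x in d.items():
            v[_IDX[k]] = x
        return cls(v)

    def __getitem__(self, state: str) -> float:
        return float(self.fractions[_IDX[state]])

    def as_dict(self) -> dict[str, float]:
        return {s: float(self.fractions[i]) for i, s in enumerate(STATES)}

    def __repr__(self) -> str:  # pragma: no cover
        inner = ", ".join(f"{s}={self.fractions[i]:.4g}" for i, s in enumerate(STATES))
        return f"PopulationState({inner})"


@dataclass
class PopulationTrajectory:
    """Time series of state fractions returned by :func:`propagate`."""

    times_s: np.ndarray
    fractions: np.ndarray           # shape (n_times, 5), rows sum to 1
    segment_boundaries_s: np.ndarray

    def state(self, name: str) -> np.ndarray:
        return self.fractions[:, _IDX[name]]

    def at(self, t: float) -> PopulationState:
        i = int(np.argmin(np.abs(self.times_s - t)))
        return PopulationState(self.fractions[i])


# ---------------------------------------------------------------------------
# generator matrix


def rate_matrix(scheme: KineticScheme, force_pn: float) -> np.ndarray:
    """Column-generator matrix Q (5x5) at the given force.

    Convention: ``dP/dt = Q @ P`` with ``Q[i, j]`` the rate of j -> i for
    i != j; every column sums to zero.
    """
    if not np.isfinite(force_pn) or force_pn < 0:
        raise InvalidParameterError(f"force must be finite and >= 0, got {force_pn}")
    Q = np.zeros((5, 5))
    conc = scheme.chaperone_conc

    def add(src: int, dst: int, rate: float) -> None:
        Q[dst, src] += rate
        Q[src, src] -= rate

    if force_pn > FORCE_REGIME_THRESHOLD_PN:
        # force-pulse regime
        add(F, EU, scheme.k_u)
        add(CU, EU, scheme.k_uc)
        add(CB, EB, scheme.k_uc)
        kon = scheme.k_on_ext * conc * scheme.kon_multiplier(force_pn)
        add(EU, EB, kon)
        add(EB, EU, scheme.k_off_ext)
    else:
        # quench regime
        add(EU, CU, scheme.k_c)
        add(CU, F, scheme.k_f0)
        add(EU, EB, scheme.k_on_ext * conc)
        add(EB, EU, scheme.k_off_ext)
        add(CU, CB, scheme.k_on_coll * conc)
        add(CB, CU, scheme.k_off_coll)
    return Q


class _SegmentPropagator:
    """exp(Q t) evaluated cheaply for many t via eigendecomposition.

    Falls back to scipy's expm when Q is ill-conditioned for
    diagonalisation (never the case for generic rate sets).
    """

    def __init__(self, Q: np.ndarray) -> None:
        self.Q = Q
        self._eig = None
        try:
            w, V = np.linalg.eig(Q)
            Vinv = np.linalg.inv(V)
            if np.linalg.cond(V) < 1e10:
                # verify against one expm evaluation
                t0 = 1.0
                approx = (V * np.exp(w * t0)) @ Vinv
                if np.max(np.abs(approx.real - expm(Q * t0))) < 1e-9:
                    self._eig = (w, V, Vinv)
        except np.linalg.LinAlgError:
            pass

    def matrix(self, t: float) -> np.ndarray:
        if t == 0:
            return np.eye(5)
        if self._eig is not None:
            w, V, Vinv = self._eig
            return ((V * np.exp(w * t)) @ Vinv).real
        return expm(self.Q * t)

    def apply(self, p: np.ndarray, t: float) -> np.ndarray:
        if self._eig is not None:
            w, V, Vinv = self._eig
            return ((V * np.exp(w * t)) @ (Vinv @ p)).real
        return expm(self.Q * t) @ p


def propagate(scheme: KineticScheme, protocol: ForceProtocol,
              init: PopulationState) -> PopulationTrajectory:
    """Propagate the population through the protocol (exact per segment).

    Returns samples on the protocol's regular time grid plus every segment
    boundary.  Total probability is conserved to better than 1e-9.
    """
    if not isinstance(init, PopulationState):
        init = PopulationState(init)
    dt = 1.0 / protocol.sampling_rate_hz
    bounds = protocol.boundaries_s
    times: list[np.ndarray] = []
    frames: list[np.ndarray] = []
    p = init.fractions.copy()
    t0 = 0.0
    for seg in protocol.segments:
        Q = rate_matrix(scheme, seg.force_pn)
        prop = _SegmentPropagator(Q)
        # local grid: 0, dt, 2dt, ..., duration (always include the end)
        n_full = int(math.floor(seg.duration_s / dt + 1e-9))
        local = np.arange(n_full + 1) * dt
        if seg.duration_s - local[-1] > 1e-12:
            local = np.append(local, seg.duration_s)
        step = prop.matrix(dt)
        out = np.empty((len(local), 5))
        cur = p
        out[0] = cur
        for i in range(1, len(local)):
            d = local[i] - local[i - 1]
            cur = step @ cur if abs(d - dt) < 1e-12 else prop.apply(cur, d)
            # guard against tiny negative round-off
            cur = np.clip(cur, 0.0, None)
            cur /= cur.sum()
            out[i] = cur
        times.append(t0 + local)
        frames.append(out)
        p = out[-1]
        t0 += seg.duration_s
    return PopulationTrajectory(np.concatenate(times), np.vstack(frames), bounds)


def _segment_end_state(scheme: KineticScheme, segments: Sequence[Segment],
                       p0: np.ndarray) -> np.ndarray:
    """State vector after propagating through ``segments`` (boundaries only)."""
    p = p0
    for seg in segments:
        prop = _SegmentPropagator(rate_matrix(scheme, seg.force_pn))
        p = np.clip(prop.apply(p, seg.duration_s), 0.0, None)
        p /= p.sum()
    return p


def predict_yield(scheme: KineticScheme, protocol: ForceProtocol,
                  init: PopulationState | None = None) -> float:
    """Refolding yield predicted by the deterministic model.

    The yield is the folded fraction at the end of the last quench segment,
    scaled by ``fold_competence`` (only folded domains produce test-pulse
    steps; collapsed domains re-extend without steps).  When ``init`` is
    omitted, leading ``unfold`` segments are skipped and the population
    starts all Extended-free at their end — the initial pulse serves to
    create the unfolded ensemble.
    """
    labels = [s.label for s in protocol.segments]
    if "quench" not in labels:
        raise ValueError("protocol has no quench segment; yield undefined")
    segs = list(protocol.segments)
    if init is None:
        while segs and segs[0].label == "unfold":
            segs.pop(0)
        p = PopulationState.pure("ext_free").fractions
    else:
        p = init.fractions
    last_q = max(i for i, s in enumerate(segs) if s.label == "quench")
    p = _segment_end_state(scheme, segs[:last_q + 1], p)
    return float(scheme.fold_competence * p[F])


def predict_yield_curve(scheme: KineticScheme, grid, *, vary: str,
                        t_ext_s: float = 0.0, extend_force_pn: float = 120.0,
                        t_q_s: float = 5.0) -> np.ndarray:
    """Predicted yield along a protocol sweep, computed incrementally.

    ``vary`` is one of ``'t_q'`` (quench-duration sweep), ``'t_ext'``
    (extended-time sweep at fixed quench) or ``'force'`` (extend-force sweep
    at fixed ``t_ext_s`` and ``t_q_s``).  Shared segments are propagated
    once, which makes chi-square evaluation over a grid cheap.
    """
    grid = np.asarray(grid, dtype=float)
    p0 = PopulationState.pure("ext_free").fractions
    out = np.empty(len(grid))
    if vary == "t_q":
        if t_ext_s > 0:
            p0 = _segment_end_state(
                scheme, [Segment("extend", extend_force_pn, t_ext_s)], p0)
        order = np.argsort(grid)
        qprop = _SegmentPropagator(rate_matrix(scheme, 0.0))
        t_prev, p = 0.0, p0
        for i in order:
            p = np.clip(qprop.apply(p, grid[i] - t_prev), 0.0, None)
            p /= p.sum()
            t_prev = grid[i]
            out[i] = p[F]
    elif vary == "t_ext":
        order = np.argsort(grid)
        eprop = _SegmentPropagator(rate_matrix(scheme, extend_force_pn))
        qprop = _SegmentPropagator(rate_matrix(scheme, 0.0))
        t_prev, p = 0.0, p0
        for i in order:
            p = np.clip(eprop.apply(p, grid[i] - t_prev), 0.0, None)
            p /= p.sum()
            t_prev = grid[i]
            pq = np.clip(qprop.apply(p, t_q_s), 0.0, None)
            out[i] = pq[F] / pq.sum()
    elif vary == "force":
        qprop = _SegmentPropagator(rate_matrix(scheme, 0.0))
        for i, f in enumerate(grid):
            p = _segment_end_state(scheme, [Segment("extend", f, t_ext_s)], p0)
            pq = np.clip(qprop.apply(p, t_q_s), 0.0, None)
            out[i] = pq[F] / pq.sum()
    else:
        raise ValueError(f"vary must be 't_q', 't_ext' or 'force', got {vary!r}")
    return scheme.fold_competence * out


# ---------------------------------------------------------------------------
# small closed forms


def equilibrium_unbound_fraction(kd_m: float, conc_m: float) -> float:
    """Equilibrium chaperone-free fraction K_d / (K_d + [chaperone]).

    With binding in equilibrium, the residual refolding yield at long
    exposure is this fraction times the no-chaperone yield.
    """
    if not kd_m > 0:
        raise InvalidParameterError(f"K_d must be > 0, got {kd_m}")
    if conc_m < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {conc_m}")
    return kd_m / (kd_m + conc_m)


def pseudo_first_order_rate(k_on: float, k_off: float, conc_m: float) -> float:
    """Binding relaxation rate k_on*[C] + k_off (1/s).

    When binding dominates the yield-versus-t_ext decay, this is the
    apparent exponential rate of that decay.
    """
    if k_on < 0 or k_off < 0 or conc_m < 0:
        raise InvalidParameterError("rates and concentration must be >= 0")
    return k_on * conc_m + k_off


def kon_multiplier_from_energy(profile, force_pn: float) -> float:
    """Dimensionless k_on multiplier exp(-ddG(F)/kBT) from an energy profile.

    ``profile`` is any object with ``forces_pn`` and ``dg_mean_kbt`` arrays
    (e.g. :class:`chapfold.dihedrals.EnergyProfile`).  ddG is measured from
    the profile minimum, so the multiplier is 1 at the minimum-energy force
    and < 1 elsewhere.  Linear interpolation between tabulated forces;
    requesting a force outside the tabulated range raises.
    """
    forces = np.asarray(profile.forces_pn, dtype=float)
    dg = np.asarray(profile.dg_mean_kbt, dtype=float)
    order = np.argsort(forces)
    forces, dg = forces[order], dg[order]
    if force_pn < forces[0] or force_pn > forces[-1]:
        raise InvalidParameterError(
            f"force {force_pn} pN outside profile range [{forces[0]}, {forces[-1]}]")
    ddg = np.interp(force_pn, forces, dg - dg.min())
    return float(np.exp(-ddg))
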