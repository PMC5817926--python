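"""Stochastic twin of the kinetic model and synthetic force-clamp data.

Generates what the AFM instrument would record: Gillespie realisations of
independent polyprotein domains under a piecewise-constant force protocol,
rendered as noisy staircase extension-versus-time traces (20-nm steps for
ubiquitin, 25-nm for Z1) and aggregated into per-recording refolding step
counts.

Because the rates are piecewise constant in time, the direct Gillespie
method is exact provided no jump straddles a segment boundary: waiting
times that overrun the current segment are discarded and the clock restarts
at the boundary with the new rates (valid by the memoryless property).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import (
    FORCE_REGIME_THRESHOLD_PN,
    STATES,
    ForceProtocol,
    KineticScheme,
    rate_matrix,
)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "RefoldingDataset",
    "simulate_domain",
    "simulate_experiment",
    "simulate_staircase_traces",
    "write_trace",
    "read_trace",
    "write_dataset",
    "read_dataset",
]

_F, _EU, _EB, _CU, _CB = range(5)

TRACE_SCHEMA = "chapfold-trace v1"
DATASET_SCHEMA = "chapfold-dataset v1"

#: Default per-domain extension contribution (nm) by state, per force regime.
#: Constant per (state, regime) — the staircase geometry is all the step
#: detector needs; worm-like-chain rendering is a noted extension point.
#: Collapsed states are mechanically labile: under pulling force they extend
#: essentially instantly and without a discrete folded-domain step, so their
#: pulse-regime length equals the extended one.
def _default_baseline(step_size_nm: float) -> dict[tuple[str, str], float]:
    return {
        ("folded", "pulse"): 0.0,
        ("ext_free", "pulse"): step_size_nm,
        ("ext_bound", "pulse"): step_size_nm,
        ("coll_free", "pulse"): step_size_nm,
        ("coll_bound", "pulse"): step_size_nm,
        ("folded", "quench"): 0.0,
        ("ext_free", "quench"): 0.0,
        ("ext_bound", "quench"): 0.0,
        ("coll_free", "quench"): 0.0,
        ("coll_bound", "quench"): 0.0,
    }


@dataclass
class SimulationConfig:
    """Experiment-level settings for the synthetic force-clamp generator.

    ``n_domains_max`` is the polyprotein length (9 for the ubiquitin
    nonamer, 8 for I27/Z1 octamers); each recording tethers a uniform
    random number of domains in ``[pickup_min, n_domains_max]``, which
    exercises the downstream step-count QC filters.
    """

    n_domains_max: int = 9
    pickup_min: int = 5
    step_size_nm: float = 20.0
    noise_sd_nm: float = 1.0
    baseline_per_state: dict[tuple[str, str], float] | None = None
    seed: int = 0
    n_recordings: int = 50

    def __post_init__(self) -> None:
        if not 1 <= self.pickup_min <= self.n_domains_max:
            raise ValueError("need 1 <= pickup_min <= n_domains_max")
        if self.step_size_nm <= 0:
            raise ValueError("step_size_nm must be > 0")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd_nm must be >= 0")

    def baseline(self) -> dict[tuple[str, str], float]:
        return (self.baseline_per_state if self.baseline_per_state is not None
                else _default_baseline(self.step_size_nm))


@dataclass
class Trajectory:
    """One synthetic recording: sampled extension trace plus ground truth."""

    time_s: np.ndarray
    force_pn: np.ndarray
    extension_nm: np.ndarray
    metadata: dict = field(default_factory=dict)
    events: list[tuple[int, float, str, str]] | None = None  # (domain, t, src, dst)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if not np.all(np.isfinite(self.extension_nm)):
            raise ValueError("extension must be finite")
        if self.events:
            t0, t1 = self.time_s[0], self.time_s[-1]
            for _, t, _, _ in self.events:
                if not t0 - 1e-9 <= t <= t1 + 1e-9:
                    raise ValueError("ground-truth event outside trace span")

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))


class RefoldingDataset:
    """Per-recording step counts for initial and test pulses.

    Wraps a DataFrame with columns ``recording_id, condition, t_q_s,
    t_ext_s, extend_force_pn, n_domains, steps_initial, steps_test,
    ext_end_initial_nm, ext_end_test_nm``.  ``steps_test <= steps_initial``
    holds for every recording that passes the extension-equality QC (a
    domain that skipped unfolding in the initial pulse but unfolds in the
    test pulse violates it and is caught by that filter).
    """

    COLUMNS = ["recording_id", "condition", "t_q_s", "t_ext_s", "extend_force_pn",
               "n_domains", "steps_initial", "steps_test",
               "ext_end_initial_nm", "ext_end_test_nm"]

    def __init__(self, records: pd.DataFrame, step_size_nm: float = 20.0,
                 n_domains_max: int = 9) -> None:
        missing = set(self.COLUMNS) - set(records.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        r = records.reset_index(drop=True)
        if ((r.steps_initial < 0).any() or (r.steps_test < 0).any()
                or (r.steps_initial > n_domains_max).any()):
            raise ValueError("step counts outside [0, n_domains_max]")
        self.records = r
        self.step_size_nm = float(step_size_nm)
        self.n_domains_max = int(n_domains_max)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        return (isinstance(other, RefoldingDataset)
                and self.step_size_nm == other.step_size_nm
                and self.n_domains_max == other.n_domains_max
                and self.records[self.COLUMNS].equals(other.records[self.COLUMNS]))


# ---------------------------------------------------------------------------
# Gillespie


def _segment_rate_tables(scheme: KineticScheme, protocol: ForceProtocol):
    """Per segment: (total exit rate, destinations, probabilities) per state."""
    tables = []
    for seg in protocol.segments:
        Q = rate_matrix(scheme, seg.force_pn)
        per_state = []
        for s in range(5):
            col = Q[:, s].copy()
            col[s] = 0.0
            total = col.sum()
            if total > 0:
                dests = np.nonzero(col)[0]
                probs = col[dests] / total
            else:
                dests = np.empty(0, dtype=int)
                probs = np.empty(0)
            per_state.append((total, dests, probs))
        tables.append(per_state)
    return tables


def simulate_domain(scheme: KineticScheme, protocol: ForceProtocol,
                    seed=None, init_state: int = _F,
                    _tables=None) -> list[tuple[float, str, str]]:
    """Exact continuous-time Markov realisation of one domain.

    Returns the jump list as ``(time_s, from_state, to_state)`` name
    tuples.  Reproducible for a given seed (int or numpy Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = _tables if _tables is not None else _segment_rate_tables(scheme, protocol)
    events: list[tuple[float, str, str]] = []
    state = init_state
    t = 0.0
    for seg, table in zip(protocol.segments, tables):
        t_end = t + seg.duration_s
        while True:
            total, dests, probs = table[state]
            if total <= 0:
                break
            wait = rng.exponential(1.0 / total)
            if t + wait >= t_end:
                break  # jump would straddle the boundary; restart there
            t += wait
            nxt = int(rng.choice(dests, p=probs)) if len(dests) > 1 else int(dests[0])
            events.append((t, STATES[state], STATES[nxt]))
            state = nxt
        t = t_end
    return events


def _state_timeline(events, init_state: int = _F):
    """(change_times, states) arrays from an event list, starting at t=0."""
    times = [0.0]
    states = [init_state]
    idx = {s: i for i, s in enumerate(STATES)}
    for t, _, dst in events:
        times.append(t)
        states.append(idx[dst])
    return np.asarray(times), np.asarray(states, dtype=int)


def _render_extension(domain_events: list, protocol: ForceProtocol,
                      baseline: dict, noise_sd: float, rng) -> Trajectory:
    dt = 1.0 / protocol.sampling_rate_hz
    bounds = protocol.boundaries_s
    grid = np.arange(int(round(bounds[-1] / dt)) + 1) * dt
    seg_idx = np.clip(np.searchsorted(bounds, grid, side="right") - 1,
                      0, len(protocol.segments) - 1)
    force = np.asarray([protocol.segments[i].force_pn for i in range(len(protocol.segments))])[seg_idx]
    regime = np.where(force > FORCE_REGIME_THRESHOLD_PN, 0, 1)  # 0=pulse 1=quench
    # baseline lookup table [state, regime]
    lut = np.asarray([[baseline[(s, "pulse")], baseline[(s, "quench")]] for s in STATES])
    ext = np.zeros_like(grid)
    for events in domain_events:
        ctimes, cstates = _state_timeline(events)
        st = cstates[np.clip(np.searchsorted(ctimes, grid, side="right") - 1,
                             0, len(cstates) - 1)]
        ext += lut[st, regime]
    if noise_sd > 0:
        ext = ext + rng.normal(0.0, noise_sd, size=grid.shape)
    segs = [{"label": s.label, "t0": float(b0), "t1": float(b1),
             "force_pn": s.force_pn}
            for s, b0, b1 in zip(protocol.segments, bounds[:-1], bounds[1:])]
    return Trajectory(grid, force.astype(float), ext,
                      metadata={"segments": segs,
                                "n_domains": len(domain_events)})


def simulate_experiment(scheme: KineticScheme, protocol: ForceProtocol,
                        config: SimulationConfig, *, condition: str = "cond0",
                        render_traces: bool = True
                        ) -> tuple[RefoldingDataset, list[Trajectory]]:
    """Simulate ``n_recordings`` polyprotein pickups under one protocol.

    Each recording draws its tethered-domain count uniformly in
    ``[pickup_min, n_domains_max]`` and its own RNG stream from the master
    seed, so individual recordings are reproducible.  Folding-incompetent
    domains (fraction ``1 - fold_competence``) evolve with ``k_f0 = 0``.
    """
    labels = [s.label for s in protocol.segments]
    if "unfold" not in labels or "test" not in labels:
        raise ValueError("protocol needs both 'unfold' and 'test' segments")
    bounds = protocol.boundaries_s
    test_start = bounds[labels.index("test")]
    init_end = bounds[labels.index("quench")] if "quench" in labels else test_start
    t_q = sum(s.duration_s for s in protocol.segments if s.label == "quench")
    t_ext = sum(s.duration_s for s in protocol.segments if s.label == "extend")
    ext_force = next((s.force_pn for s in protocol.segments if s.label == "extend"),
                     protocol.segments[0].force_pn)

    tables = _segment_rate_tables(scheme, protocol)
    tables_inc = (_segment_rate_tables(scheme.replace(k_f0=0.0), protocol)
                  if scheme.fold_competence < 1.0 else tables)
    baseline = config.baseline()
    lut_pulse = {s: baseline[(s, "pulse")] for s in STATES}

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_recordings)
    rows = []
    traces: list[Trajectory] = []
    for rec, child in enumerate(children):
        rng = np.random.default_rng(child)
        n_dom = int(rng.integers(config.pickup_min, config.n_domains_max + 1))
        domain_events = []
        steps_initial = steps_test = 0
        end_init_states = []
        end_test_states = []
        for _ in range(n_dom):
            competent = rng.random() < scheme.fold_competence
            ev = simulate_domain(scheme, protocol, rng,
                                 _tables=tables if competent else tables_inc)
            domain_events.append(ev)
            for t, src, dst in ev:
                if src == "folded" and dst == "ext_free":
                    if t < init_end:
                        steps_initial += 1
                    elif t >= test_start:
                        steps_test += 1
            ctimes, cstates = _state_timeline(ev)
            end_init_states.append(cstates[np.searchsorted(ctimes, init_end,
                                                           side="right") - 1])
            end_test_states.append(cstates[-1])
        ext_end_initial = sum(lut_pulse[STATES[s]] for s in end_init_states)
        ext_end_test = sum(lut_pulse[STATES[s]] for s in end_test_states)
        rows.append((rec, condition, t_q, t_ext, ext_force, n_dom,
                     steps_initial, steps_test, ext_end_initial, ext_end_test))
        if render_traces:
            tr = _render_extension(domain_events, protocol, baseline,
                                   config.noise_sd_nm, rng)
            tr.metadata.update({"recording_id": rec, "condition": condition,
                                "seed": config.seed})
            tr.events = [(d, t, src, dst) for d, ev in enumerate(domain_events)
                         for (t, src, dst) in ev]
            traces.append(tr)
    df = pd.DataFrame(rows, columns=RefoldingDataset.COLUMNS)
    return RefoldingDataset(df, config.step_size_nm, config.n_domains_max), traces


def simulate_staircase_traces(scheme: KineticScheme, protocol: ForceProtocol,
                              config: SimulationConfig) -> list[Trajectory]:
    """Unfold-pulse-only recordings for unfolding-kinetics studies.

    Every tethered domain starts folded; the trace is the noisy staircase
    of stepwise unfolding at the pulse force.  Ground-truth unfolding times
    are attached for detector benchmarking.
    """
    tables = _segment_rate_tables(scheme, protocol)
    baseline = config.baseline()
    children = np.random.SeedSequence(config.seed).spawn(config.n_recordings)
    traces = []
    for rec, child in enumerate(children):
        rng = np.random.default_rng(child)
        n_dom = int(rng.integers(config.pickup_min, config.n_domains_max + 1))
        domain_events = [simulate_domain(scheme, protocol, rng, _tables=tables)
                         for _ in range(n_dom)]
        tr = _render_extension(domain_events, protocol, baseline,
                               config.noise_sd_nm, rng)
        tr.metadata.update({"recording_id": rec, "seed": config.seed})
        tr.events = [(d, t, src, dst) for d, ev in enumerate(domain_events)
                     for (t, src, dst) in ev]
        traces.append(tr)
    return traces


# ---------------------------------------------------------------------------
# file formats (plain text, '#'-prefixed metadata headers)


def write_trace(trace: Trajectory, path) -> None:
    """TSV with metadata header: columns time_s, force_pN, extension_nm."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {TRACE_SCHEMA}\n")
        fh.write(f"# metadata={json.dumps(trace.metadata)}\n")
        fh.write("time_s\tforce_pN\textension_nm\n")
        np.savetxt(fh, np.column_stack([trace.time_s, trace.force_pn,
                                        trace.extension_nm]),
                   fmt="%.6f\t%.3f\t%.4f")


def read_trace(path) -> Trajectory:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        first = fh.readline().strip()
        if first != f"# {TRACE_SCHEMA}":
            raise ValueError(f"{path}: not a {TRACE_SCHEMA} file")
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("metadata="):
                meta = json.loads(body[len("metadata="):])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t")
    return Trajectory(df["time_s"].to_numpy(), df["force_pN"].to_numpy(),
                      df["extension_nm"].to_numpy(), metadata=meta)


def write_dataset(dataset: RefoldingDataset, path) -> None:
    """CSV with the RefoldingDataset columns plus a schema header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {DATASET_SCHEMA}\n")
        fh.write(f"# step_size_nm={dataset.step_size_nm!r} "
                 f"n_domains_max={dataset.n_domains_max}\n")
        dataset.records.to_csv(fh, index=False)


def read_dataset(path) -> RefoldingDataset:
    path = Path(path)
    step_size, n_max = 20.0, 9
    with path.open() as fh:
        first = fh.readline().strip()
        if first != f"# {DATASET_SCHEMA}":
            raise ValueError(f"{path}: not a {DATASET_SCHEMA} file")
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("step_size_nm="):
                    step_size = float(tok.split("=", 1)[1])
                elif tok.startswith("n_domains_max="):
                    n_max = int(tok.split("=", 1)[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return RefoldingDataset(df, step_size, n_max)
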