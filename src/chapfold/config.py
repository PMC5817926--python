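"""Run configuration, pipeline orchestration and result files.

A single YAML file describes a whole in-silico experiment: the kinetic
scheme, the protocol grids (quench-time, extended-time, force sweeps),
simulation settings, fit settings and output paths.  Unknown keys are
rejected with their dotted location, so typos fail loudly.  Units follow
one convention everywhere: seconds, piconewtons, molar, rates in 1/s or
1/(M s), lengths in nm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fitting import ChaperoneBindingModel, YieldCurveData
from .kinetics import ForceProtocol, KineticScheme
from .motifs import scan_dnaj_consensus
from .simulate import (RefoldingDataset, SimulationConfig, simulate_experiment,
                       write_dataset, write_trace)
from .traces import QCSettings, fit_yield_curve, refolding_yield

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("chapfold")


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


_SCHEME_KEYS = {"k_u", "k_c", "k_f0", "k_uc", "k_on_ext", "k_off_ext",
                "k_on_coll", "k_off_coll", "chaperone_conc",
                "fold_competence", "free"}
_PROTOCOL_KEYS = {"unfold_force_pn", "unfold_s", "extend_force_pn", "test_s",
                  "t_q_grid", "t_ext_grid", "force_grid", "t_q_default",
                  "t_ext_default", "sampling_rate_hz"}
_SIM_KEYS = {"n_recordings", "n_domains_max", "pickup_min", "step_size_nm",
             "noise_sd_nm", "render_traces"}
_ANALYSIS_KEYS = {"min_steps_initial", "extension_tol_frac", "n_boot"}
_FIT_KEYS = {"n_starts"}
_SCAN_KEYS = {"sequence", "offset", "seq_id"}
_TOP_KEYS = {"seed", "log_level", "scheme", "protocol", "simulation",
             "analysis", "fit", "scan", "output_dir"}


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} at {where or '<top level>'}")


@dataclass
class RunConfig:
    """Validated run configuration; see the packaged example YAML layout."""

    scheme: KineticScheme
    free_rates: list[str]
    unfold_force_pn: float = 120.0
    unfold_s: float = 5.0
    extend_force_pn: float = 120.0
    test_s: float = 5.0
    t_q_grid: list[float] = field(default_factory=lambda: [0.5, 1, 2, 5, 10, 15])
    t_ext_grid: list[float] = field(default_factory=list)
    force_grid: list[float] = field(default_factory=list)
    t_q_default: float = 5.0
    t_ext_default: float = 0.0
    sampling_rate_hz: float = 1000.0
    n_recordings: int = 50
    n_domains_max: int = 9
    pickup_min: int = 5
    step_size_nm: float = 20.0
    noise_sd_nm: float = 1.0
    render_traces: bool = False
    min_steps_initial: int = 5
    extension_tol_frac: float = 0.10
    n_boot: int = 500
    n_starts: int = 8
    scan_sequence: str | None = None
    scan_offset: int = 1
    scan_seq_id: str = "seq"
    seed: int = 0
    log_level: str = "INFO"
    output_dir: Path = Path("chapfold_results")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, _TOP_KEYS, "")
        sch = dict(raw.get("scheme", {}))
        _check_keys(sch, _SCHEME_KEYS, "scheme")
        free = list(sch.pop("free", []))
        scheme = KineticScheme(**sch)
        proto = dict(raw.get("protocol", {}))
        _check_keys(proto, _PROTOCOL_KEYS, "protocol")
        sim = dict(raw.get("simulation", {}))
        _check_keys(sim, _SIM_KEYS, "simulation")
        ana = dict(raw.get("analysis", {}))
        _check_keys(ana, _ANALYSIS_KEYS, "analysis")
        fit = dict(raw.get("fit", {}))
        _check_keys(fit, _FIT_KEYS, "fit")
        scan = dict(raw.get("scan", {}))
        _check_keys(scan, _SCAN_KEYS, "scan")
        return cls(
            scheme=scheme, free_rates=free,
            **{k: v for k, v in proto.items()},
            **{k: v for k, v in sim.items()},
            **{k: v for k, v in ana.items()},
            **{k: v for k, v in fit.items()},
            scan_sequence=scan.get("sequence"),
            scan_offset=scan.get("offset", 1),
            scan_seq_id=scan.get("seq_id", "seq"),
            seed=raw.get("seed", 0),
            log_level=raw.get("log_level", "INFO"),
            output_dir=Path(raw.get("output_dir", "chapfold_results")),
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["output_dir"] = str(d["output_dir"])
        d["scheme"].pop("kon_force_profile", None)
        return d

    def config_hash(self) -> str:
        """Stable hash identifying this configuration (stamped on outputs).

        Covers the scientific content only: output location and log level
        do not change what is computed.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("log_level", None)
        canon = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- protocol builders ---------------------------------------------------

    def protocol_for(self, *, t_q: float | None = None,
                     t_ext: float | None = None,
                     force: float | None = None) -> ForceProtocol:
        return ForceProtocol.force_quench(
            unfold_force_pn=self.unfold_force_pn, unfold_s=self.unfold_s,
            t_ext_s=self.t_ext_default if t_ext is None else t_ext,
            extend_force_pn=self.extend_force_pn if force is None else force,
            t_q_s=self.t_q_default if t_q is None else t_q,
            test_s=self.test_s, sampling_rate_hz=self.sampling_rate_hz)

    def conditions(self):
        """(label, kwargs) pairs covering the configured protocol grids."""
        for t_q in self.t_q_grid:
            yield f"tq_{t_q:g}", {"t_q": t_q}
        for t_ext in self.t_ext_grid:
            yield f"text_{t_ext:g}", {"t_ext": t_ext}
        for f in self.force_grid:
            yield f"force_{f:g}", {"force": f, "t_ext": self.t_ext_default}


# ---------------------------------------------------------------------------


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, stages=("simulate", "analyze", "fit")) -> dict:
    """Execute the selected pipeline stages; returns the result bundle.

    Writes versioned JSON results plus intermediate dataset/trace files to
    ``config.output_dir``.  Every output carries the config hash, so
    identical configs and seeds reproduce byte-identical files.  A stage
    failure aborts with :class:`PipelineError` naming the stage.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    bundle: dict = {"schema": "chapfold-results v1", "version": __version__,
                    "config_hash": chash, "seed": config.seed}
    datasets: dict[str, RefoldingDataset] = {}

    if "simulate" in stages:
        t0 = time.perf_counter()
        try:
            for i, (label, kw) in enumerate(config.conditions()):
                proto = config.protocol_for(**kw)
                sim = SimulationConfig(
                    n_domains_max=config.n_domains_max,
                    pickup_min=config.pickup_min,
                    step_size_nm=config.step_size_nm,
                    noise_sd_nm=config.noise_sd_nm,
                    seed=int(np.random.SeedSequence(
                        [config.seed, i]).generate_state(1)[0] % (2 ** 31)),
                    n_recordings=config.n_recordings)
                ds, traces = simulate_experiment(
                    config.scheme, proto, sim, condition=label,
                    render_traces=config.render_traces)
                datasets[label] = ds
                write_dataset(ds, out / f"dataset_{label}.csv")
                for tr in traces:
                    write_trace(tr, out / f"trace_{label}_"
                                f"{tr.metadata['recording_id']:04d}.tsv")
            log.info("simulate: %d conditions in %.2f s", len(datasets),
                     time.perf_counter() - t0)
        except Exception as exc:
            raise PipelineError("simulate", exc) from exc

    if "analyze" in stages:
        try:
            from .simulate import read_dataset
            if not datasets:
                for p in sorted(out.glob("dataset_*.csv")):
                    datasets[p.stem.removeprefix("dataset_")] = read_dataset(p)
            if not datasets:
                raise FileNotFoundError("no datasets to analyze")
            qc = QCSettings(config.min_steps_initial, config.extension_tol_frac)
            analysis: dict[str, dict] = {}
            for label, ds in datasets.items():
                y, sem = refolding_yield(ds, qc, n_boot=config.n_boot,
                                         seed=config.seed)
                kept = ds.records
                analysis[label] = {
                    "yield": y, "sem": sem,
                    "n_recordings": int(len(kept)),
                    "n_domains": int(kept.steps_initial.sum()),
                    "t_q_s": float(kept.t_q_s.iloc[0]),
                    "t_ext_s": float(kept.t_ext_s.iloc[0]),
                    "extend_force_pn": float(kept.extend_force_pn.iloc[0]),
                }
            # per-family exponential fits
            fits = {}
            tq = sorted((v["t_q_s"], v["yield"], v["sem"])
                        for k, v in analysis.items() if k.startswith("tq_"))
            if len(tq) >= 3:
                g, y, s = map(np.asarray, zip(*tq))
                fr = fit_yield_curve(g, y, s, form="saturating")
                fits["t_q"] = {"form": fr.form, "rate": fr.rate,
                               "rate_se": fr.rate_se, "plateau": fr.amplitude,
                               "success": fr.success}
            te = sorted((v["t_ext_s"], v["yield"], v["sem"])
                        for k, v in analysis.items() if k.startswith("text_"))
            if len(te) >= 3:
                g, y, s = map(np.asarray, zip(*te))
                fr = fit_yield_curve(g, y, s, form="decaying")
                fits["t_ext"] = {"form": fr.form, "rate": fr.rate,
                                 "rate_se": fr.rate_se, "plateau": fr.offset,
                                 "success": fr.success}
            bundle["analysis"] = analysis
            bundle["fits"] = fits
            _write_json({"schema": "chapfold-analysis v1",
                         "config_hash": chash, "conditions": analysis,
                         "fits": fits}, out / "analysis.json")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("analyze", exc) from exc

    if "fit" in stages:
        try:
            analysis = bundle.get("analysis")
            if analysis is None:
                analysis = json.loads((out / "analysis.json").read_text())["conditions"]
            curves = []
            tq = sorted((v["t_q_s"], v["yield"], v["sem"], v["t_ext_s"])
                        for k, v in analysis.items() if k.startswith("tq_"))
            if tq:
                g, y, s, tx = map(np.asarray, zip(*tq))
                curves.append(YieldCurveData("t_q", g, y, s,
                                             t_ext_s=float(tx[0]),
                                             extend_force_pn=config.extend_force_pn))
            te = sorted((v["t_ext_s"], v["yield"], v["sem"])
                        for k, v in analysis.items() if k.startswith("text_"))
            if te:
                g, y, s = map(np.asarray, zip(*te))
                curves.append(YieldCurveData("t_ext", g, y, s,
                                             t_q_s=config.t_q_default,
                                             extend_force_pn=config.extend_force_pn))
            fo = sorted((v["extend_force_pn"], v["yield"], v["sem"])
                        for k, v in analysis.items() if k.startswith("force_"))
            if fo:
                g, y, s = map(np.asarray, zip(*fo))
                curves.append(YieldCurveData("force", g, y, s,
                                             t_ext_s=config.t_ext_default,
                                             t_q_s=config.t_q_default))
            if not curves:
                raise ValueError("no yield curves available for fitting")
            free = config.free_rates or ["k_on_ext", "k_off_ext"]
            model = ChaperoneBindingModel(curves, config.scheme, free=free)
            res = model.fit(seed=config.seed, n_starts=config.n_starts)
            fitted = {"schema": "chapfold-fit v1", "config_hash": chash,
                      "params": res.params, "chi2": res.chi2,
                      "converged": res.converged,
                      "kd_ext_M": res.kd_ext, "kd_coll_M": res.kd_coll,
                      "bse_log10": res.bse_log10}
            bundle["fit"] = fitted
            _write_json(fitted, out / "fitted_params.json")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("fit", exc) from exc

    if "scan" in stages:
        try:
            if not config.scan_sequence:
                raise ValueError("scan stage requires scan.sequence in config")
            hits = scan_dnaj_consensus(config.scan_sequence,
                                       offset=config.scan_offset,
                                       seq_id=config.scan_seq_id)
            payload = {"schema": "chapfold-scan v1", "config_hash": chash,
                       "matches": [dataclasses.asdict(h) for h in hits]}
            bundle["scan"] = payload
            _write_json(payload, out / "motif_matches.json")
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("scan", exc) from exc

    _write_json({k: v for k, v in bundle.items() if k != "analysis_obj"},
                out / "results.json")
    return bundle
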