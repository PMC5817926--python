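"""Free-energy cost of remodeling backbone dihedrals to chaperone-bound values.

A stretched peptide held at force F samples backbone dihedral angles
(phi, psi) from force-dependent Ramachandran distributions.  Binding by an
Hsp40 constrains five consecutive (phi, psi) couples of the consensus
fragment (ubiquitin LYS48..ASP52) to the values they take in the
chaperone-substrate complex.  The remodeling cost at force F is

    dG(F) = - sum_residues  ln p_{residue, F}(phi*, psi*)        [k_B T]

with p the estimated (phi, psi) density at force F and (phi*, psi*) the
bound-reference angles.  Replicate simulations give a mean and SD per
force; the profile is conventionally normalized so its minimum over forces
is zero.  The force at which dG is minimal is where binding is cheapest —
an energy profile can be converted into a force-dependent association-rate
multiplier with :func:`chapfold.kinetics.kon_multiplier_from_energy`.

Samples normally come from MD; :func:`generate_dihedral_samples` provides a
synthetic stand-in drawing from von Mises mixtures whose basin weights
shift with force.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import i0e

__all__ = [
    "CONSENSUS_RESIDUES",
    "DihedralSampleSet",
    "BoundReference",
    "EnergyProfile",
    "TorusDensity",
    "VonMisesBasin",
    "estimate_density",
    "delta_g",
    "generate_dihedral_samples",
    "ramachandran_classify",
    "ubiquitin_demo_basins",
    "ubiquitin_demo_reference",
]

#: The five constrained (phi, psi) couples of the ubiquitin consensus
#: fragment; flanking residues are excluded.
CONSENSUS_RESIDUES = ("LYS48", "GLN49", "LEU50", "GLU51", "ASP52")

_DEG = math.pi / 180.0


def _wrap(a):
    """Wrap angles (degrees) into (-180, 180]."""
    return -((-np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0)


class DihedralSampleSet:
    """(phi, psi) samples per (residue, force, replicate), degrees.

    Backed by a DataFrame with columns ``residue, force_pn, replicate,
    phi_deg, psi_deg``.  The same residue set must be present at every
    force, with at least one replicate each.
    """

    COLUMNS = ["residue", "force_pn", "replicate", "phi_deg", "psi_deg"]

    def __init__(self, df: pd.DataFrame) -> None:
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        ang = df[["phi_deg", "psi_deg"]].to_numpy()
        if np.any(ang <= -180.0 - 1e-9) or np.any(ang > 180.0 + 1e-9):
            raise ValueError("angles must lie in (-180, 180] degrees")
        self.df = df.reset_index(drop=True)
        res_by_force = self.df.groupby("force_pn")["residue"].agg(frozenset)
        if len(set(res_by_force)) > 1:
            raise ValueError("every force must carry the same residue set")

    @property
    def forces_pn(self) -> np.ndarray:
        return np.sort(self.df.force_pn.unique())

    @property
    def residues(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.df.residue))

    @property
    def replicates(self) -> np.ndarray:
        return np.sort(self.df.replicate.unique())

    def samples(self, residue: str, force_pn: float, replicate) -> np.ndarray:
        sel = self.df[(self.df.residue == residue)
                      & (self.df.force_pn == force_pn)
                      & (self.df.replicate == replicate)]
        return sel[["phi_deg", "psi_deg"]].to_numpy()

    def to_tsv(self, path) -> None:
        Path(path).write_text(self.df.to_csv(sep="\t", index=False))

    @classmethod
    def from_tsv(cls, path) -> "DihedralSampleSet":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class BoundReference:
    """Bound-state (phi*, psi*) per constrained residue, degrees.

    In the original workflow these come from a long simulation of the
    chaperone-substrate complex; here they are configuration inputs.
    """

    angles: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for res, (phi, psi) in self.angles.items():
            if not (-180 < phi <= 180 and -180 < psi <= 180):
                raise ValueError(f"{res}: reference angles out of range")


@dataclass
class EnergyProfile:
    """dG(F) curve: per-force mean and SD (k_BT) across replicates."""

    forces_pn: np.ndarray
    dg_mean_kbt: np.ndarray
    dg_sd_kbt: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.forces_pn = np.asarray(self.forces_pn, dtype=float)
        self.dg_mean_kbt = np.asarray(self.dg_mean_kbt, dtype=float)
        self.dg_sd_kbt = np.asarray(self.dg_sd_kbt, dtype=float)
        if np.any(self.dg_sd_kbt < 0):
            raise ValueError("SDs must be >= 0")
        if self.normalized and abs(self.dg_mean_kbt.min()) > 1e-9:
            raise ValueError("normalized profile must have minimum exactly 0")

    def normalize(self) -> "EnergyProfile":
        """Shift so the minimum over forces is exactly 0 (SDs unchanged)."""
        m = self.dg_mean_kbt.min()
        return EnergyProfile(self.forces_pn, self.dg_mean_kbt - m,
                             self.dg_sd_kbt.copy(), normalized=True)

    @property
    def min_force_pn(self) -> float:
        return float(self.forces_pn[int(np.argmin(self.dg_mean_kbt))])

    def to_json_dict(self) -> dict:
        return {"forces_pn": self.forces_pn.tolist(),
                "dg_mean_kbt": self.dg_mean_kbt.tolist(),
                "dg_sd_kbt": self.dg_sd_kbt.tolist(),
                "normalized": self.normalized}


# ---------------------------------------------------------------------------
# density estimation on the torus


class TorusDensity:
    """Periodic 2D density on (-180, 180]^2, in probability per degree^2."""

    def __init__(self, evaluate: Callable[[np.ndarray, np.ndarray], np.ndarray]):
        self._evaluate = evaluate

    def __call__(self, phi_deg, psi_deg) -> np.ndarray:
        return self._evaluate(_wrap(phi_deg), _wrap(psi_deg))

    def log(self, phi_deg, psi_deg) -> np.ndarray:
        return np.log(self(phi_deg, psi_deg))


def estimate_density(samples: np.ndarray, method: str = "histogram", *,
                     bin_width_deg: float = 5.0, pseudocount: float = 1.0,
                     kde_kappa: float = 50.0) -> TorusDensity:
    """Estimate the (phi, psi) density from samples of one residue/force/replicate.

    ``method='histogram'`` bins on a regular grid (default 5 degrees) with a
    Laplace pseudo-count spread over all bins, so the estimate is strictly
    positive and integrates to one; ``method='kde'`` uses a product von
    Mises kernel (exact periodicity, no binning).  Needs >= 100 samples.
    """
    s = np.asarray(samples, dtype=float)
    if s.ndim != 2 or s.shape[1] != 2:
        raise ValueError("samples must be an (n, 2) array of (phi, psi)")
    if len(s) < 100:
        raise ValueError(f"need >= 100 samples, got {len(s)}")
    phi = _wrap(s[:, 0])
    psi = _wrap(s[:, 1])
    if method == "histogram":
        nbins = int(round(360.0 / bin_width_deg))
        if not math.isclose(nbins * bin_width_deg, 360.0):
            raise ValueError("bin width must divide 360 degrees")
        edges = np.linspace(-180.0, 180.0, nbins + 1)
        H, _, _ = np.histogram2d(phi, psi, bins=[edges, edges])
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        total = H.sum() + pseudocount * nbins * nbins
        P = (H + pseudocount) / total / bin_width_deg ** 2

        def ev(ph, ps):
            i = np.clip(((np.asarray(ph) + 180.0) / bin_width_deg).astype(int),
                        0, nbins - 1)
            j = np.clip(((np.asarray(ps) + 180.0) / bin_width_deg).astype(int),
                        0, nbins - 1)
            val = P[i, j]
            if pseudocount == 0 and np.any(val <= 0):
                raise ValueError(
                    "reference falls in a zero-support bin; use a positive "
                    "pseudocount (regularization) or the 'kde' method")
            return val

        return TorusDensity(ev)
    if method == "kde":
        kap = float(kde_kappa)
        # kernels evaluated as exp(kappa (cos d - 1)) <= 1; the matching
        # normalization uses the scaled Bessel i0e(k) = I0(k) exp(-k), so
        # large kappa stays finite
        norm = (2 * math.pi * i0e(kap)) ** 2  # per rad^2, one kernel

        def ev(ph, ps):
            ph = np.atleast_1d(ph)[:, None] * _DEG
            ps = np.atleast_1d(ps)[:, None] * _DEG
            k = np.exp(kap * (np.cos(ph - phi * _DEG) - 1.0)
                       + kap * (np.cos(ps - psi * _DEG) - 1.0))
            dens_rad = k.mean(axis=1) / norm
            out = dens_rad * _DEG ** 2
            return out if out.size > 1 else float(out[0])

        return TorusDensity(ev)
    raise ValueError(f"unknown method {method!r}")


def delta_g(samples: DihedralSampleSet, ref: BoundReference, *,
            method: str = "histogram", normalize: bool = True,
            **density_kw) -> EnergyProfile:
    """Remodeling free-energy profile dG(F) from dihedral samples.

    Per replicate, dG(F) = -sum over reference residues of the estimated
    log-density at (phi*, psi*); the mean and SD are taken across
    replicates (SD before normalization), and the mean profile is then
    shifted so its minimum over forces is zero.
    """
    res_needed = set(ref.angles)
    if not res_needed <= set(samples.residues):
        missing = sorted(res_needed - set(samples.residues))
        raise ValueError(f"reference residues absent from samples: {missing}")
    forces = samples.forces_pn
    means, sds = [], []
    for f in forces:
        per_rep = []
        for rep in samples.replicates:
            dg = 0.0
            for res, (phi_s, psi_s) in ref.angles.items():
                dens = estimate_density(samples.samples(res, f, rep),
                                        method=method, **density_kw)
                dg -= float(np.log(dens(phi_s, psi_s)))
            per_rep.append(dg)
        means.append(np.mean(per_rep))
        sds.append(np.std(per_rep, ddof=1) if len(per_rep) > 1 else 0.0)
    prof = EnergyProfile(forces, np.asarray(means), np.asarray(sds))
    return prof.normalize() if normalize else prof


# ---------------------------------------------------------------------------
# synthetic sample generator (MD stand-in)


@dataclass(frozen=True)
class VonMisesBasin:
    """One Ramachandran basin: independent von Mises in phi and psi.

    ``weight`` maps force (pN) to an unnormalized mixture weight — e.g. a
    logistic switch that populates the beta basin at high force.
    """

    mu_phi_deg: float
    mu_psi_deg: float
    kappa_phi: float
    kappa_psi: float
    weight: Callable[[float], float]

    def log_density(self, phi_deg: float, psi_deg: float) -> float:
        """Analytic log density (per degree^2) of this single component."""
        lp = (self.kappa_phi * (math.cos((phi_deg - self.mu_phi_deg) * _DEG) - 1.0)
              - math.log(2 * math.pi * i0e(self.kappa_phi)))
        ls = (self.kappa_psi * (math.cos((psi_deg - self.mu_psi_deg) * _DEG) - 1.0)
              - math.log(2 * math.pi * i0e(self.kappa_psi)))
        return lp + ls + 2 * math.log(_DEG)


def generate_dihedral_samples(basin_spec: Mapping[str, Sequence[VonMisesBasin]],
                              forces_pn, n_per_replicate: int = 2000,
                              replicates: int = 5, seed: int = 0
                              ) -> DihedralSampleSet:
    """Draw synthetic (phi, psi) samples from force-dependent basin mixtures.

    ``basin_spec`` maps residue -> components; at each force the component
    weights are evaluated and renormalized.  One RNG stream per
    (force, replicate) pair derived from ``seed`` keeps replicates
    reproducible individually.
    """
    forces = np.asarray(forces_pn, dtype=float)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(forces) * replicates))
    rows = []
    for f in forces:
        for rep in range(replicates):
            rng = np.random.default_rng(next(children))
            for res, basins in basin_spec.items():
                w = np.asarray([max(float(b.weight(f)), 0.0) for b in basins])
                if w.sum() <= 0:
                    raise ValueError(
                        f"weights of {res} at {f} pN are not normalizable")
                w = w / w.sum()
                comp = rng.choice(len(basins), size=n_per_replicate, p=w)
                for ci, b in enumerate(basins):
                    n_c = int(np.sum(comp == ci))
                    if n_c == 0:
                        continue
                    phi = _wrap(np.degrees(rng.vonmises(
                        b.mu_phi_deg * _DEG, max(b.kappa_phi, 1e-12), n_c)))
                    psi = _wrap(np.degrees(rng.vonmises(
                        b.mu_psi_deg * _DEG, max(b.kappa_psi, 1e-12), n_c)))
                    rows.append(pd.DataFrame({
                        "residue": res, "force_pn": f, "replicate": rep,
                        "phi_deg": phi, "psi_deg": psi}))
    return DihedralSampleSet(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Ramachandran regions


#: Rectangular region boundaries (phi_lo, phi_hi, psi_lo, psi_hi], degrees.
#: Coarse by design: enough to say whether a residue sits in the
#: beta/polyproline-II "top left corner", a helical basin, or elsewhere.
RAMACHANDRAN_REGIONS: dict[str, tuple[float, float, float, float]] = {
    "beta/PPII": (-180.0, -45.0, 45.0, 180.0),
    "alphaR": (-180.0, 0.0, -120.0, 45.0),
    "alphaL": (0.0, 180.0, -60.0, 90.0),
}


def ramachandran_classify(phi_deg: float, psi_deg: float) -> str:
    """Region label for a (phi, psi) pair: beta/PPII, alphaR, alphaL or other."""
    phi = float(_wrap(phi_deg))
    psi = float(_wrap(psi_deg))
    for label, (plo, phi_hi, slo, shi) in RAMACHANDRAN_REGIONS.items():
        if plo <= phi < phi_hi and slo <= psi < shi:
            return label
    return "other"


# ---------------------------------------------------------------------------
# demonstration scenario


def _logistic(force_mid: float, steep: float, lo: float = 0.02,
              hi: float = 1.0, rising: bool = True) -> Callable[[float], float]:
    def w(f: float) -> float:
        x = 1.0 / (1.0 + math.exp(-(f - force_mid) / steep))
        return lo + (hi - lo) * (x if rising else 1.0 - x)
    return w


def ubiquitin_demo_reference() -> BoundReference:
    """Synthetic bound-state reference angles for the consensus couples.

    Chosen intermediate between the low-force basins of the outer residues
    and the beta basin favoured under high force by the central ones, so
    the remodeling cost is minimal at intermediate force.  These are
    synthetic stand-in values, not measured complex geometry.
    """
    return BoundReference({
        "LYS48": (-95.0, 60.0),
        "GLN49": (-110.0, 120.0),
        "LEU50": (-110.0, 120.0),
        "GLU51": (-95.0, 55.0),
        "ASP52": (-90.0, 50.0),
    })


def ubiquitin_demo_basins() -> dict[str, list[VonMisesBasin]]:
    """Force-dependent basin mixtures emulating the stretched consensus fragment.

    GLN49/LEU50 (beta-sheet couple) move into the extended beta basin as
    force rises; LYS48/GLU51/ASP52 leave their relaxed low-force basins at
    high force.  With :func:`ubiquitin_demo_reference` the resulting dG(F)
    is U-shaped with an interior minimum near 150 pN.
    """
    kap = 18.0
    spec: dict[str, list[VonMisesBasin]] = {}
    for res in ("GLN49", "LEU50"):
        spec[res] = [
            VonMisesBasin(-70.0, -20.0, kap, kap, _logistic(150, 45, rising=False)),
            VonMisesBasin(-130.0, 140.0, kap, kap, _logistic(150, 45, rising=True)),
        ]
    for res in ("LYS48", "GLU51", "ASP52"):
        spec[res] = [
            VonMisesBasin(-80.0, 30.0, kap, kap, _logistic(150, 45, rising=False)),
            VonMisesBasin(-150.0, 155.0, kap, kap, _logistic(150, 45, rising=True)),
        ]
    return spec
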