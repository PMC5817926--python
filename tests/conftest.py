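"""Shared fixtures: reference kinetic schemes and protocols.

The ubiquitin reference rates are the measured no-chaperone values
(unfolding 0.93/s at 120 pN, folding 0.52/s with fast collapse and a 75%
plateau); the DnaJ/DnaK schemes add binding constants consistent with the
reported dissociation constants (K_d(ext) = 9.4e-7 M for DnaJ,
K_d(coll) = 1.4e-7 M for DnaK) and the observed yield-decay rate 0.27/s
at 5 uM DnaJ.
"""

import numpy as np
import pytest

from chapfold import ForceProtocol, KineticScheme

UBI_KU = 0.93          # 1/s at 120 pN
UBI_KF0 = 0.52         # 1/s, collapsed -> folded
UBI_KC = 10.0          # 1/s, fast collapse on quench
UBI_COMPETENCE = 0.75  # long-t_q plateau of the refolding yield

DNAJ_CONC = 5e-6       # M
DNAJ_KON_EXT = 0.27 / (DNAJ_CONC + 9.4e-7)   # -> decay rate 0.27/s at 5 uM
DNAJ_KOFF_EXT = DNAJ_KON_EXT * 9.4e-7        # -> K_d(ext) = 9.4e-7 M

DNAK_KON_COLL = 1.5e5                        # 1/(M s)
DNAK_KOFF_COLL = DNAK_KON_COLL * 1.4e-7      # -> K_d(coll) = 1.4e-7 M


@pytest.fixture
def ubiquitin_scheme() -> KineticScheme:
    return KineticScheme(k_u=UBI_KU, k_c=UBI_KC, k_f0=UBI_KF0,
                         fold_competence=UBI_COMPETENCE)


@pytest.fixture
def dnaj_scheme(ubiquitin_scheme) -> KineticScheme:
    return ubiquitin_scheme.replace(k_on_ext=DNAJ_KON_EXT,
                                    k_off_ext=DNAJ_KOFF_EXT,
                                    chaperone_conc=DNAJ_CONC)


@pytest.fixture
def dnak_scheme(ubiquitin_scheme) -> KineticScheme:
    return ubiquitin_scheme.replace(k_on_coll=DNAK_KON_COLL,
                                    k_off_coll=DNAK_KOFF_COLL,
                                    chaperone_conc=5e-6)


@pytest.fixture
def quench_protocol() -> ForceProtocol:
    return ForceProtocol.force_quench(t_q_s=5.0)


def random_scheme(rng: np.random.Generator) -> KineticScheme:
    """Randomized but physical scheme for property tests."""
    return KineticScheme(
        k_u=rng.uniform(0.1, 5), k_c=rng.uniform(0.5, 30),
        k_f0=rng.uniform(0.05, 2), k_uc=rng.uniform(5, 100),
        k_on_ext=10 ** rng.uniform(3, 6), k_off_ext=10 ** rng.uniform(-3, 0),
        k_on_coll=10 ** rng.uniform(3, 6), k_off_coll=10 ** rng.uniform(-3, 0),
        chaperone_conc=10 ** rng.uniform(-7, -5),
        fold_competence=rng.uniform(0.3, 1.0))
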