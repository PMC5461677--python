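"""Bundled example dataset: a south-eastern Australian survey of parasitoid
communities on eight *Cardiaspina*/*Spondyliaspis* psyllid populations.

Three tables are encoded:

* emergence counts of adult wasps per host population, morphospecies and sex;
* maximum between-population cytb p-distance comparisons per morphospecies;
* per-stratum results of the morphospecies-specific multiplex PCR screen of
  post-emergence mummies (informative / uninformative counts and which other
  species' DNA was consistently co-detected).

The four major morphospecies are two primary parasitoids (P1, P2), one
hyperparasitoid (H) and one heteronomous hyperparasitoid (HH); APH is a rare
aphelinid found only as females.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .seqdiv import DivergenceMatrix
from .trophic import MummyRecord

HOSTS = (
    "albitextura",
    "densitexta",
    "fiscella",
    "maniformis",
    "tenuitela",
    "vittaformis",
    "GB",
    "Spondyliaspis",
)

MORPHOSPECIES = ("P1", "P2", "H", "HH")
PSYLLAEPHAGUS = ("P1", "P2", "HH")
PANEL_TARGETS = ("P1", "P2", "H", "HH")

#: adult wasps emerged from capsule mummies or collected from bagged nymphs,
#: keyed (morphospecies, sex); P1 and APH were found as females only
EMERGENCE_COUNTS: dict[str, dict[tuple[str, str], int]] = {
    "albitextura": {
        ("P1", "female"): 67, ("P2", "male"): 2, ("P2", "female"): 10,
        ("H", "male"): 17, ("H", "female"): 50, ("HH", "male"): 0,
        ("HH", "female"): 10, ("APH", "female"): 0,
    },
    "densitexta": {
        ("P1", "female"): 75, ("P2", "male"): 2, ("P2", "female"): 3,
        ("H", "male"): 2, ("H", "female"): 2, ("HH", "male"): 0,
        ("HH", "female"): 0, ("APH", "female"): 0,
    },
    "fiscella": {
        ("P1", "female"): 1, ("P2", "male"): 2, ("P2", "female"): 2,
        ("H", "male"): 59, ("H", "female"): 60, ("HH", "male"): 4,
        ("HH", "female"): 9, ("APH", "female"): 0,
    },
    "maniformis": {
        ("P1", "female"): 12, ("P2", "male"): 29, ("P2", "female"): 21,
        ("H", "male"): 0, ("H", "female"): 0, ("HH", "male"): 6,
        ("HH", "female"): 10, ("APH", "female"): 0,
    },
    "tenuitela": {
        ("P1", "female"): 53, ("P2", "male"): 0, ("P2", "female"): 0,
        ("H", "male"): 6, ("H", "female"): 14, ("HH", "male"): 0,
        ("HH", "female"): 8, ("APH", "female"): 1,
    },
    "vittaformis": {
        ("P1", "female"): 5, ("P2", "male"): 0, ("P2", "female"): 0,
        ("H", "male"): 0, ("H", "female"): 0, ("HH", "male"): 0,
        ("HH", "female"): 0, ("APH", "female"): 0,
    },
    "GB": {
        ("P1", "female"): 301, ("P2", "male"): 57, ("P2", "female"): 27,
        ("H", "male"): 26, ("H", "female"): 26, ("HH", "male"): 10,
        ("HH", "female"): 9, ("APH", "female"): 0,
    },
    "Spondyliaspis": {
        ("P1", "female"): 0, ("P2", "male"): 4, ("P2", "female"): 9,
        ("H", "male"): 3, ("H", "female"): 0, ("HH", "male"): 2,
        ("HH", "female"): 5, ("APH", "female"): 2,
    },
}


def emergence_table() -> pd.DataFrame:
    """Emergence counts as a hosts x (morphospecies, sex) table."""
    cols = sorted({k for v in EMERGENCE_COUNTS.values() for k in v})
    df = pd.DataFrame(
        [[EMERGENCE_COUNTS[h][c] for c in cols] for h in HOSTS],
        index=list(HOSTS),
        columns=pd.MultiIndex.from_tuples(cols, names=["morphospecies", "sex"]),
    )
    return df


def total_emerged() -> int:
    return int(emergence_table().to_numpy().sum())


def sex_counts(morphospecies: str) -> tuple[int, int]:
    """Total (female, male) adults of a morphospecies across all hosts."""
    df = emergence_table()
    f = int(df[morphospecies].get("female", pd.Series(0, index=df.index)).sum())
    m = int(df[morphospecies].get("male", pd.Series(0, index=df.index)).sum())
    return f, m


# ---------------------------------------------------------------------------
# maximum between-population cytb divergence (%), per morphospecies;
# diagonal entries are maximum within-population divergences

_P1 = {
    ("albitextura", "albitextura"): 0.0,
    ("albitextura", "densitexta"): 0.3,
    ("albitextura", "maniformis"): 17.4,
    ("albitextura", "tenuitela"): 0.0,
    ("albitextura", "vittaformis"): 2.3,
    ("albitextura", "GB"): 17.2,
    ("densitexta", "densitexta"): 0.3,
    ("densitexta", "maniformis"): 17.4,
    ("densitexta", "tenuitela"): 0.3,
    ("densitexta", "vittaformis"): 2.6,
    ("densitexta", "GB"): 17.2,
    ("maniformis", "maniformis"): 0.0,
    ("maniformis", "tenuitela"): 17.4,
    ("maniformis", "vittaformis"): 18.6,
    ("maniformis", "GB"): 13.1,
    ("tenuitela", "tenuitela"): 0.0,
    ("tenuitela", "vittaformis"): 2.3,
    ("tenuitela", "GB"): 17.2,
    ("vittaformis", "vittaformis"): 0.6,
    ("vittaformis", "GB"): 18.6,
    ("GB", "GB"): 0.9,
}

_P2 = {
    ("albitextura", "albitextura"): 0.3,
    ("albitextura", "densitexta"): 0.3,
    ("albitextura", "fiscella"): 10.5,
    ("albitextura", "maniformis"): 11.6,
    ("albitextura", "GB"): 0.3,
    ("albitextura", "Spondyliaspis"): 14.8,
    ("densitexta", "densitexta"): 0.0,
    ("densitexta", "fiscella"): 10.5,
    ("densitexta", "maniformis"): 11.6,
    ("densitexta", "GB"): 0.3,
    ("densitexta", "Spondyliaspis"): 14.8,
    ("fiscella", "fiscella"): 0.6,
    ("fiscella", "maniformis"): 8.4,
    ("fiscella", "GB"): 10.5,
    ("fiscella", "Spondyliaspis"): 14.8,
    ("maniformis", "maniformis"): 0.0,
    ("maniformis", "GB"): 11.6,
    ("maniformis", "Spondyliaspis"): 16.3,
    ("GB", "GB"): 0.3,
    ("GB", "Spondyliaspis"): 14.8,
    ("Spondyliaspis", "Spondyliaspis"): 0.6,
}

_H = {
    ("albitextura", "albitextura"): 0.9,
    ("albitextura", "densitexta"): 1.2,
    ("albitextura", "fiscella"): 2.3,
    ("albitextura", "tenuitela"): 0.6,
    ("albitextura", "GB"): 3.8,
    ("albitextura", "Spondyliaspis"): 3.5,
    ("densitexta", "densitexta"): 0.6,
    ("densitexta", "fiscella"): 1.7,
    ("densitexta", "tenuitela"): 0.9,
    ("densitexta", "GB"): 3.2,
    ("densitexta", "Spondyliaspis"): 3.5,
    ("fiscella", "fiscella"): 0.0,
    ("fiscella", "tenuitela"): 2.0,
    ("fiscella", "GB"): 2.0,
    ("fiscella", "Spondyliaspis"): 2.9,
    ("tenuitela", "tenuitela"): 0.6,
    ("tenuitela", "GB"): 3.5,
    ("tenuitela", "Spondyliaspis"): 3.2,
    ("GB", "GB"): 0.9,
    ("GB", "Spondyliaspis"): 4.9,
    ("Spondyliaspis", "Spondyliaspis"): 0.0,
}

_HH = {
    ("albitextura", "albitextura"): 0.9,
    ("albitextura", "fiscella"): 17.2,
    ("albitextura", "maniformis"): 15.1,
    ("albitextura", "tenuitela"): 0.9,
    ("albitextura", "GB"): 15.4,
    ("albitextura", "Spondyliaspis"): 16.9,
    ("fiscella", "fiscella"): 0.6,
    ("fiscella", "maniformis"): 4.7,
    ("fiscella", "tenuitela"): 17.4,
    ("fiscella", "GB"): 2.9,
    ("fiscella", "Spondyliaspis"): 3.2,
    ("maniformis", "maniformis"): 0.6,
    ("maniformis", "tenuitela"): 15.7,
    ("maniformis", "GB"): 1.7,
    ("maniformis", "Spondyliaspis"): 3.2,
    ("tenuitela", "tenuitela"): 0.3,
    ("tenuitela", "GB"): 15.7,
    ("tenuitela", "Spondyliaspis"): 17.2,
    ("GB", "GB"): 0.0,
    ("GB", "Spondyliaspis"): 2.0,
    ("Spondyliaspis", "Spondyliaspis"): 0.0,
}

DIVERGENCE_PAIRS: dict[str, dict[tuple[str, str], float]] = {
    "P1": _P1,
    "P2": _P2,
    "H": _H,
    "HH": _HH,
}


def divergence_matrix_for(morphospecies: str) -> DivergenceMatrix:
    """Between-population maximum-divergence matrix for one morphospecies."""
    pairs = DIVERGENCE_PAIRS[morphospecies]
    labels = sorted({l for pair in pairs for l in pair})
    n = len(labels)
    values = np.zeros((n, n))
    for (a, b), v in pairs.items():
        i, j = labels.index(a), labels.index(b)
        values[i, j] = values[j, i] = v
    return DivergenceMatrix(labels=labels, values=values, statistic="max")


# ---------------------------------------------------------------------------
# multiplex PCR screen of post-emergence mummies:
# (host, emerged species, sex, other species consistently co-detected,
#  informative, uninformative, printed detection success %)

MUMMY_SCREEN: tuple[tuple[str, str, str, str | None, int, int, int], ...] = (
    ("albitextura", "P1", "female", None, 20, 40, 33),
    ("albitextura", "P2", "female", None, 7, 3, 70),
    ("albitextura", "P2", "male", None, 2, 0, 100),
    ("albitextura", "H", "female", "P2", 20, 5, 80),
    ("albitextura", "H", "male", "P2", 15, 2, 88),
    ("albitextura", "HH", "female", None, 5, 5, 50),
    ("fiscella", "P1", "female", None, 0, 1, 0),
    ("fiscella", "P2", "female", None, 2, 0, 100),
    ("fiscella", "P2", "male", None, 2, 0, 100),
    ("fiscella", "H", "female", "P2", 20, 7, 74),
    ("fiscella", "H", "male", "P2", 20, 6, 77),
    ("fiscella", "HH", "female", None, 8, 1, 89),
    ("fiscella", "HH", "male", "P1", 4, 0, 100),
    ("maniformis", "P1", "female", None, 2, 10, 17),
    ("maniformis", "P2", "female", None, 17, 4, 81),
    ("maniformis", "P2", "male", None, 20, 3, 87),
    ("maniformis", "HH", "female", None, 8, 2, 80),
    ("maniformis", "HH", "male", "P1", 4, 2, 67),
    ("tenuitela", "P1", "female", None, 8, 45, 15),
    ("tenuitela", "H", "female", "P2", 14, 0, 100),
    ("tenuitela", "H", "male", "P2", 4, 2, 67),
    ("tenuitela", "HH", "female", None, 5, 3, 63),
    ("GB", "P1", "female", None, 20, 162, 11),
    ("GB", "P2", "female", None, 20, 5, 80),
    ("GB", "P2", "male", None, 20, 4, 83),
    ("GB", "H", "female", "P2", 20, 6, 77),
    ("GB", "H", "male", "P2", 20, 6, 77),
    ("GB", "HH", "female", None, 8, 1, 89),
    ("GB", "HH", "male", "P1", 3, 7, 30),
    ("Spondyliaspis", "P2", "female", None, 3, 6, 33),
    ("Spondyliaspis", "P2", "male", None, 4, 0, 100),
    ("Spondyliaspis", "H", "male", "P2", 2, 1, 67),
    ("Spondyliaspis", "HH", "female", None, 4, 1, 80),
    ("Spondyliaspis", "HH", "male", "P1", 2, 0, 100),
)


def screening_table() -> pd.DataFrame:
    return pd.DataFrame(
        MUMMY_SCREEN,
        columns=[
            "host_species",
            "emerged_species",
            "emerged_sex",
            "other_species",
            "informative",
            "uninformative",
            "detection_success",
        ],
    )


def mummy_records() -> list[MummyRecord]:
    """Expand the screening summary into one record per mummy.

    Informative mummies carry psyllid DNA, the emerged species' DNA and the
    consistently co-detected other species' DNA.  Uninformative mummies
    alternate between a failed psyllid PCR and a failed emerged-species PCR;
    their co-detection flags are left unset.
    """
    records = []
    for host, sp, sex, other, n_inf, n_uninf, _ in MUMMY_SCREEN:
        for i in range(n_inf):
            det = {t: False for t in PANEL_TARGETS}
            det[sp] = True
            if other is not None:
                det[other] = True
            records.append(
                MummyRecord(
                    mummy_id=f"{host}-{sp}-{sex}-inf{i + 1}",
                    host_species=host,
                    emerged_species=sp,
                    emerged_sex=sex,
                    psyllid_dna=True,
                    detected=det,
                )
            )
        for i in range(n_uninf):
            psyllid_failed = i % 2 == 0
            det = {t: False for t in PANEL_TARGETS}
            det[sp] = psyllid_failed  # emerged-species PCR failed otherwise
            records.append(
                MummyRecord(
                    mummy_id=f"{host}-{sp}-{sex}-uninf{i + 1}",
                    host_species=host,
                    emerged_species=sp,
                    emerged_sex=sex,
                    psyllid_dna=not psyllid_failed,
                    detected=det,
                )
            )
    return records
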