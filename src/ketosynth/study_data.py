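"""Study-level data for the glioma ketogenic-therapy evidence synthesis.

Two packaged fixtures carry the published summary data:

* ``table1_studies.csv`` — one row per study (3 human cohorts, 17 animal
  experiments): per-arm RMST ± SE and the RMST ratio (MR) ± SE.
* ``table2_cells.csv`` — the 5-species × 4-intervention grid of
  ln(MR) ± SD that the hierarchical model consumes, with 12 observed
  cells and 8 missing.

The cell grid, not a recomputation from the study table, is the
canonical model input; :func:`assemble_matrix` exists for new data and
sensitivity reruns (cells with several studies are pooled with the
random-effects machinery in :mod:`ketosynth.pooling`).
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .km_rmst import MREstimate, RMSTEstimate
from .pooling import PoolingSpec, pool_random_effects

__all__ = [
    "SPECIES",
    "INTERVENTIONS",
    "REPLICATE_STUDIES",
    "RIEGER_HUMAN_STUDY",
    "StudyRecord",
    "CellEstimate",
    "EvidenceMatrix",
    "load_table1",
    "load_table2",
    "assemble_matrix",
    "drop_studies",
]

#: Fixed species ordering (model row index i).
SPECIES = ("Humans", "Athymic mice", "C57BL mice", "SCID mice", "Fisher rats")
#: Fixed intervention ordering (model column index j): ketogenic diet or
#: calorie restriction, alone or combined with another treatment.
INTERVENTIONS = ("KD", "KD+", "CR", "CR+")

#: Animal experiments that replicated another experiment's tumour model;
#: removed together in one sensitivity analysis.
REPLICATE_STUDIES = frozenset({"Stafford 2010", "Lussier 2016", "Marsh 2008"})
#: The human cohort whose control arm was patients without stable ketosis
#: rather than a standard-diet group; removed in another sensitivity run.
RIEGER_HUMAN_STUDY = frozenset({"Rieger 2015"})

_CHECKSUMS = {
    "table1_studies.csv": "596514d743b64abccbc781da1ae0ef3821ceee66c58c13dd9b535230ef5235aa",
    "table2_cells.csv": "11072affc90f5f6c5b5461193f504f9c52fc6f9423f2157fdf684a540dd4d9fd",
}


@dataclass(frozen=True)
class StudyRecord:
    """One study arm-pair: per-arm RMST summaries and their ratio."""

    study_id: str
    year: int
    first_author: str
    species: str
    intervention: str
    n_treat: int
    n_ctrl: int
    rmst_treat: RMSTEstimate
    rmst_ctrl: RMSTEstimate
    mr: MREstimate
    source: str = ""

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.intervention not in INTERVENTIONS:
            raise ValueError(f"unknown intervention {self.intervention!r}")
        if self.n_treat <= 0 or self.n_ctrl <= 0:
            raise ValueError("group sizes must be positive")


@dataclass(frozen=True)
class CellEstimate:
    """ln(MR) with its standard deviation for one species × intervention cell."""

    ln_mr: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("cell standard deviation must be positive")


@dataclass(frozen=True)
class EvidenceMatrix:
    """The 5 × 4 grid of cell estimates the hierarchical model consumes.

    ``y`` and ``sd`` are 5 × 4 float arrays with NaN in unobserved
    cells; ``mask`` is True where a cell is observed.
    """

    y: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        sd = np.asarray(self.sd, dtype=float)
        if y.shape != (5, 4) or sd.shape != (5, 4):
            raise ValueError("evidence matrix must be 5 species x 4 interventions")
        if not np.array_equal(np.isnan(y), np.isnan(sd)):
            raise ValueError("y and sd must share one missingness pattern")
        if np.any(sd[~np.isnan(sd)] <= 0):
            raise ValueError("observed cells need positive standard deviations")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "sd", sd)

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.y)

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def cell(self, species: str, intervention: str) -> Optional[CellEstimate]:
        i, j = SPECIES.index(species), INTERVENTIONS.index(intervention)
        if np.isnan(self.y[i, j]):
            return None
        return CellEstimate(float(self.y[i, j]), float(self.sd[i, j]))

    def without_cell(self, species: str, intervention: str) -> "EvidenceMatrix":
        i, j = SPECIES.index(species), INTERVENTIONS.index(intervention)
        y, sd = self.y.copy(), self.sd.copy()
        y[i, j] = sd[i, j] = np.nan
        return EvidenceMatrix(y, sd)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, sp in enumerate(SPECIES):
            for j, iv in enumerate(INTERVENTIONS):
                rows.append(
                    {
                        "species": sp,
                        "intervention": iv,
                        "ln_mr": self.y[i, j],
                        "sd": self.sd[i, j],
                        "observed": bool(self.mask[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def _fixture_path(name: str):
    res = importlib.resources.files("ketosynth").joinpath("data", name)
    data = res.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise RuntimeError(f"fixture {name} is corrupted (checksum mismatch)")
    return res


def load_table1() -> list[StudyRecord]:
    """The 20 packaged study records (3 human cohorts, 17 animal experiments)."""
    res = _fixture_path("table1_studies.csv")
    with importlib.resources.as_file(res) as path:
        df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        treat = RMSTEstimate(row.rmst_treat, row.se_treat, horizon=math.inf)
        ctrl = RMSTEstimate(row.rmst_ctrl, row.se_ctrl, horizon=math.inf)
        mr = MREstimate(mr=row.mr, se_mr=row.se_mr)
        records.append(
            StudyRecord(
                study_id=row.study_id,
                year=int(row.year),
                first_author=row.first_author,
                species=row.species,
                intervention=row.intervention,
                n_treat=int(row.n_treat),
                n_ctrl=int(row.n_ctrl),
                rmst_treat=treat,
                rmst_ctrl=ctrl,
                mr=mr,
                source=row.source,
            )
        )
    return records


_COLS = {"KD": "KD", "KD+": "KDplus", "CR": "CR", "CR+": "CRplus"}


def load_table2() -> EvidenceMatrix:
    """The packaged 5 × 4 ln(MR) ± SD grid (12 observed cells, 8 missing)."""
    res = _fixture_path("table2_cells.csv")
    with importlib.resources.as_file(res) as path:
        df = pd.read_csv(path).set_index("species")
    y = np.full((5, 4), np.nan)
    sd = np.full((5, 4), np.nan)
    for i, sp in enumerate(SPECIES):
        for j, iv in enumerate(INTERVENTIONS):
            val = df.loc[sp, f"{_COLS[iv]}_ln_mr"]
            err = df.loc[sp, f"{_COLS[iv]}_sd"]
            if pd.notna(val):
                y[i, j], sd[i, j] = float(val), float(err)
    return EvidenceMatrix(y, sd)


def assemble_matrix(
    records: Sequence[StudyRecord],
    pooling_prior: str = "half_normal",
) -> EvidenceMatrix:
    """Build a model input grid from study records.

    Cells backed by a single study carry that study's ln(MR) ± SE; cells
    with several studies are pooled by Bayesian random-effects
    meta-analysis under the named between-study prior (``uniform``,
    ``half_normal`` or ``dumouchel``); cells with no study stay missing.
    """
    for r in records:
        if r.species not in SPECIES or r.intervention not in INTERVENTIONS:
            raise ValueError(
                f"record {r.study_id!r} has unknown species/intervention "
                f"({r.species!r}, {r.intervention!r})"
            )
    spec = PoolingSpec(tau_prior=pooling_prior)
    y = np.full((5, 4), np.nan)
    sd = np.full((5, 4), np.nan)
    for i, sp in enumerate(SPECIES):
        for j, iv in enumerate(INTERVENTIONS):
            cell_records = [
                r for r in records if r.species == sp and r.intervention == iv
            ]
            if not cell_records:
                continue
            estimates = [
                CellEstimate(r.mr.ln_mr, r.mr.se_ln_mr) for r in cell_records
            ]
            pooled = pool_random_effects(estimates, spec)
            y[i, j], sd[i, j] = pooled.ln_mr, pooled.sd
    return EvidenceMatrix(y, sd)


def drop_studies(
    records: Sequence[StudyRecord], names: Iterable[str]
) -> list[StudyRecord]:
    """Filtered copy of ``records`` with the named studies removed."""
    names = set(names)
    known = {r.study_id for r in records}
    unknown = names - known
    if unknown:
        raise KeyError(f"unknown study ids: {sorted(unknown)}")
    return [r for r in records if r.study_id not in names]
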