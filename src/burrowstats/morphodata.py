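"""Morpho-functional indices and regression-ready datasets.

Three percent indices quantify the degree of development of limb-bone
superstructures used in digging:

* **RDT** — relative position of the deltoid tuberosity along the humerus:
  ``landmark / humerus_length * 100``.  A more distal insertion increases the
  in-lever of arm retraction.
* **IFA** — index of fossorial ability: olecranon length relative to the
  functional (remaining) ulna length, ``olecranon / (ulna - olecranon) * 100``.
* **TJI** — tibio-fibular junction index: position of the ossified junction
  along the tibia, ``junction / tibia_length * 100``.

A superstructure can be genuinely absent (e.g. the naked mole-rat lacks a
projected deltoid tuberosity and a distal tibio-fibular fusion); absence is a
distinct missing state, never coded as zero, and such rows are dropped when a
regression dataset is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .treeio import PhyloTree

__all__ = [
    "compute_rdt",
    "compute_ifa",
    "compute_tji",
    "read_measurements",
    "indices_from_measurements",
    "build_dataset",
    "RegressionDataset",
    "MEASUREMENT_COLUMNS",
    "INDEX_NAMES",
]

MEASUREMENT_COLUMNS = [
    "specimen_id",
    "species",
    "sex",
    "age_class",
    "body_mass_g",
    "bone",
    "total_length_mm",
    "landmark_mm",
    "landmark_absent",
]

INDEX_NAMES = ("RDT", "IFA", "TJI")

#: which bone carries which index
_BONE_INDEX = {"humerus": "RDT", "ulna": "IFA", "tibia-fibula": "TJI"}


def compute_rdt(humerus_length: float, dt_landmark: float) -> float:
    """Relative deltoid-tuberosity position, percent of humerus length."""
    if humerus_length <= 0:
        raise ValueError(f"humerus length must be positive, got {humerus_length}")
    if not 0 <= dt_landmark <= humerus_length:
        raise ValueError(
            f"DT landmark {dt_landmark} outside [0, humerus length {humerus_length}]"
        )
    return dt_landmark / humerus_length * 100.0


def compute_ifa(olecranon_length: float, ulna_total_length: float) -> float:
    """Index of fossorial ability: olecranon over functional ulna length."""
    if ulna_total_length <= 0:
        raise ValueError(f"ulna length must be positive, got {ulna_total_length}")
    if not 0 < olecranon_length < ulna_total_length:
        raise ValueError(
            f"olecranon {olecranon_length} must lie strictly inside "
            f"(0, ulna length {ulna_total_length})"
        )
    return olecranon_length / (ulna_total_length - olecranon_length) * 100.0


def compute_tji(tibia_length: float, junction_landmark: float) -> float:
    """Tibio-fibular junction position, percent of tibia length."""
    if tibia_length <= 0:
        raise ValueError(f"tibia length must be positive, got {tibia_length}")
    if not 0 <= junction_landmark <= tibia_length:
        raise ValueError(
            f"junction landmark {junction_landmark} outside [0, tibia length {tibia_length}]"
        )
    return junction_landmark / tibia_length * 100.0


_COMPUTE = {"RDT": compute_rdt, "IFA": compute_ifa, "TJI": compute_tji}


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a per-specimen bone-measurement CSV."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV missing columns: {missing}")
    bad = set(df["bone"]) - set(_BONE_INDEX) - {"femur"}
    if bad:
        raise ValueError(f"unknown bone values: {sorted(bad)}")
    if (df["total_length_mm"] <= 0).any():
        raise ValueError("non-positive total_length_mm")
    present = df["landmark_absent"].astype(int) == 0
    lm = df.loc[present, "landmark_mm"]
    if ((lm < 0) | (lm > df.loc[present, "total_length_mm"])).any():
        raise ValueError("landmark_mm outside [0, total_length_mm] on a present-structure row")
    return df


def indices_from_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen index table (columns: specimen_id, species, index, value,
    body_mass_g).  Rows whose superstructure is flagged absent get NaN values.
    Femur rows carry no index and are ignored.
    """
    rows = []
    for _, r in df.iterrows():
        index = _BONE_INDEX.get(r["bone"])
        if index is None:
            continue
        if int(r["landmark_absent"]):
            value = math.nan
        else:
            value = _COMPUTE[index](float(r["total_length_mm"]), float(r["landmark_mm"])) \
                if index != "IFA" else compute_ifa(float(r["landmark_mm"]), float(r["total_length_mm"]))
        rows.append(
            {
                "specimen_id": r["specimen_id"],
                "species": r["species"],
                "index": index,
                "value": value,
                "body_mass_g": r["body_mass_g"],
            }
        )
    return pd.DataFrame(rows, columns=["specimen_id", "species", "index", "value", "body_mass_g"])


@dataclass
class RegressionDataset:
    """Per-individual regression rows for one index.

    ``y`` is the natural log of the index, ``x`` the natural log body mass (g)
    centered at the retained-rows mean (``center``); ``species_idx`` codes each
    row by position in ``species`` (tree tip order restricted to the observed
    species).
    """

    index: str
    y: np.ndarray
    x: np.ndarray
    species_idx: np.ndarray
    species: list
    center: float

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": [self.species[s] for s in self.species_idx],
                "y_log_index": self.y,
                "x_centered_log_bm": self.x,
            }
        )


def build_dataset(records: pd.DataFrame, index: str, tree: PhyloTree) -> RegressionDataset:
    """Build the regression dataset for one index from an index-record table.

    Rows with a missing index value are dropped (this is how a species lacking
    the superstructure is excluded from the model).  Species are coded in tree
    tip order so the rows align with the phylogenetic correlation matrix.
    """
    if index not in INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}; expected one of {INDEX_NAMES}")
    sub = records[records["index"] == index].copy()
    sub = sub[np.isfinite(sub["value"].astype(float))]
    if len(sub) == 0:
        raise ValueError(f"no usable rows for index {index}")
    if (sub["body_mass_g"].astype(float) <= 0).any() or sub["body_mass_g"].isna().any():
        raise ValueError("body mass must be present and positive for every retained row")
    tip_order = tree.tip_labels
    present = set(sub["species"])
    missing = sorted(present - set(tip_order))
    if missing:
        raise ValueError(f"species not in tree: {missing}")
    species = [t for t in tip_order if t in present]
    code = {sp: k for k, sp in enumerate(species)}
    y = np.log(sub["value"].astype(float).to_numpy())
    logbm = np.log(sub["body_mass_g"].astype(float).to_numpy())
    center = float(logbm.mean())
    return RegressionDataset(
        index=index,
        y=y,
        x=logbm - center,
        species_idx=np.array([code[s] for s in sub["species"]], dtype=int),
        species=species,
        center=center,
    )
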