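"""Domain types and I/O for descriptor tables and packaged reference fixtures.

The central container is :class:`DescriptorTable`: one row per NO-carrier
molecule, twelve quantum-chemical descriptors, the experimental homolysis
bond dissociation energy (BDE, kcal/mol) of the Y-NO bond (Y = C, N, O, S)
and train/test metadata.  Two read-only fixtures ship with the package:

* a per-molecule deviation table (calculated minus experimental BDE,
  kcal/mol) for 92 molecules under six computational protocols, and
* self-organizing-map cluster labels for the twelve descriptors at a
  ladder of training-step counts, for two DFT basis sets.

Both fixtures are plain CSV, checksummed on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Canonical descriptor order; every label vector and feature matrix in the
#: package follows it.  dH_homo is the DFT-calculated homolysis BDE itself
#: (kcal/mol); Q_* are atomic partial charges (e); N_X the heavy-atom count;
#: mu the dipole moment; alpha the polarizability; E_* orbital energies and
#: dE the HOMO-LUMO gap.
CANONICAL_DESCRIPTORS: tuple[str, ...] = (
    "dH_homo",
    "Q_Y",
    "Q_N",
    "Q_O",
    "N_X",
    "mu",
    "alpha",
    "E_HOMO-1",
    "E_HOMO",
    "E_LUMO",
    "E_LUMO+1",
    "dE",
)

Y_TYPES = ("C", "N", "O", "S", "other")
SPLITS = ("train", "test")

#: Deviation columns of the packaged 92-molecule fixture, in printed order:
#: raw DFT for two basis sets, then the RBF correction fed with all twelve
#: descriptors, then the correction fed with the SOFM-selected subset.
DEVIATION_METHODS: tuple[str, ...] = (
    "b3lyp_631gd",
    "b3lyp_sto3g",
    "rbfnn_631gd",
    "rbfnn_sto3g",
    "sofm_rbfnn_631gd",
    "sofm_rbfnn_sto3g",
)

_FIXTURE_SHA256 = {
    "table1_deviations.csv": "ddfe660124e730b6a5cb97da16e5148a29f429c94c08f4f549abea488fef4009",
    "table2_cluster_labels.csv": "4efa55e246956b62401d26a0ad67f7f9b9a5402a57bf20c40ff9d1046442ffff",
}


class ValidationError(ValueError):
    """A table violated a structural invariant; the message names the offender."""


class FixtureChecksumError(RuntimeError):
    """A packaged fixture does not match its recorded SHA-256 digest."""


@dataclass(frozen=True)
class DescriptorTable:
    """Validated molecules-by-descriptors table.

    Wraps a :class:`pandas.DataFrame` with columns ``molecule_id``,
    ``y_type``, ``split``, ``expt_bde`` and the twelve canonical
    descriptors, in that order.  Row order is preserved from the source.
    """

    frame: pd.DataFrame = field(repr=False)
    #: tables meant for model fitting need >= 2 training rows; auxiliary
    #: all-test tables (e.g. extrapolation sets) relax this
    require_train_rows: bool = True

    REQUIRED_COLUMNS = ("molecule_id", "y_type", "split", "expt_bde") + CANONICAL_DESCRIPTORS

    def __post_init__(self) -> None:
        df = self.frame
        for col in self.REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"missing column {col!r}")
        ids = df["molecule_id"].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate molecule_id {dup!r}")
        bad_y = set(df["y_type"]) - set(Y_TYPES)
        if bad_y:
            raise ValidationError(f"unknown y_type values {sorted(bad_y)!r}")
        bad_split = set(df["split"]) - set(SPLITS)
        if bad_split:
            raise ValidationError(f"unknown split values {sorted(bad_split)!r}")
        numeric = ("expt_bde",) + CANONICAL_DESCRIPTORS
        for col in numeric:
            values = pd.to_numeric(df[col], errors="coerce")
            if values.isna().any():
                row = df.loc[values.isna(), "molecule_id"].iloc[0]
                raise ValidationError(f"non-numeric or missing value in column {col!r} (molecule {row!r})")
        if self.require_train_rows and int((df["split"] == "train").sum()) < 2:
            raise ValidationError("need at least 2 training rows")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def molecule_ids(self) -> list[str]:
        return self.frame["molecule_id"].astype(str).tolist()

    @property
    def train_mask(self) -> np.ndarray:
        return (self.frame["split"] == "train").to_numpy()

    @property
    def expt_bde(self) -> np.ndarray:
        return self.frame["expt_bde"].to_numpy(dtype=float)

    def descriptor_matrix(self, features: Iterable[str] | None = None) -> np.ndarray:
        """Molecules x features matrix in canonical (or requested) order."""
        cols = list(features) if features is not None else list(CANONICAL_DESCRIPTORS)
        unknown = set(cols) - set(CANONICAL_DESCRIPTORS)
        if unknown:
            raise ValidationError(f"unknown descriptors {sorted(unknown)!r}")
        return self.frame[cols].to_numpy(dtype=float)

    def descriptor_profiles(self, standardize: bool = True) -> np.ndarray:
        """Descriptors x molecules matrix (each row one descriptor profile).

        With ``standardize=True`` each profile is z-scored across molecules,
        which makes descriptor clustering scale-free.
        """
        profiles = self.descriptor_matrix().T
        if standardize:
            mean = profiles.mean(axis=1, keepdims=True)
            sd = profiles.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            profiles = (profiles - mean) / sd
        return profiles

    def to_csv(self, path: str | Path) -> None:
        # %.17g guarantees float64 round-trips bit-exactly through text
        self.frame.to_csv(path, index=False, float_format="%.17g")


@dataclass(frozen=True)
class DeviationTable:
    """Per-molecule deviations (calculated - experimental, kcal/mol)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        for col in ("molecule_id", "is_test") + DEVIATION_METHODS:
            if col not in df.columns:
                raise ValidationError(f"missing column {col!r}")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    def deviations(self, method: str, subset: str = "all") -> np.ndarray:
        """Deviation column for one method; ``subset`` in {all, train, test}."""
        if method not in DEVIATION_METHODS:
            raise ValidationError(f"unknown method {method!r}")
        df = self.frame
        if subset == "train":
            df = df[df["is_test"] == 0]
        elif subset == "test":
            df = df[df["is_test"] == 1]
        elif subset != "all":
            raise ValidationError(f"unknown subset {subset!r}")
        return df[method].to_numpy(dtype=float)


@dataclass(frozen=True)
class ClusterLabelRecord:
    """Winning-neuron index per descriptor for one basis set / step count."""

    basis: str
    training_steps: int
    labels: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.labels) != set(CANONICAL_DESCRIPTORS):
            raise ValidationError("labels must cover exactly the canonical 12 descriptors")
        if self.training_steps < 1:
            raise ValidationError("training_steps must be positive")
        for name, lab in self.labels.items():
            if not 1 <= int(lab) <= 24:
                raise ValidationError(f"label {lab} for {name!r} outside neuron grid 1..24")

    def label_vector(self) -> tuple[int, ...]:
        """Labels in canonical descriptor order."""
        return tuple(int(self.labels[name]) for name in CANONICAL_DESCRIPTORS)


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read and validate a descriptor CSV (comma separated, ``.`` decimal, header)."""
    df = pd.read_csv(path, dtype={"molecule_id": str}, float_precision="round_trip")
    return DescriptorTable(df)


def write_descriptor_table(table: DescriptorTable, path: str | Path) -> None:
    table.to_csv(path)


def concat_tables(*tables: DescriptorTable) -> DescriptorTable:
    """Stack tables row-wise (e.g. a base table plus an extrapolation set)."""
    frames = [t.frame for t in tables]
    return DescriptorTable(pd.concat(frames, ignore_index=True))


def _fixture_bytes(name: str) -> bytes:
    data = resources.files("sofmrbf.fixtures").joinpath(name).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _FIXTURE_SHA256[name]:
        raise FixtureChecksumError(
            f"fixture {name!r} is corrupted: sha256 {digest} != {_FIXTURE_SHA256[name]}"
        )
    return data


def load_table1_fixture() -> DeviationTable:
    """Packaged 92-molecule deviation table (six methods, kcal/mol).

    The twelve molecules held out as the neural-network test set are flagged
    ``is_test``.
    """
    from io import BytesIO

    df = pd.read_csv(BytesIO(_fixture_bytes("table1_deviations.csv")))
    if len(df) != 92:
        raise FixtureChecksumError(f"expected 92 rows, found {len(df)}")
    return DeviationTable(df)


def load_table2_fixture() -> list[ClusterLabelRecord]:
    """Packaged SOFM cluster labels: 7 step counts x 2 basis sets."""
    from io import BytesIO

    df = pd.read_csv(BytesIO(_fixture_bytes("table2_cluster_labels.csv")))
    records = []
    for _, row in df.iterrows():
        labels = {name: int(row[name]) for name in CANONICAL_DESCRIPTORS}
        records.append(
            ClusterLabelRecord(basis=str(row["basis"]), training_steps=int(row["training_steps"]), labels=labels)
        )
    if len(records) != 14:
        raise FixtureChecksumError(f"expected 14 records, found {len(records)}")
    return records
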