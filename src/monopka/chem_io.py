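"""Reading and writing the chemical file formats the pKa pipeline touches.

Everything downstream consumes :class:`MoleculeRecord` objects: an RDKit
molecule plus its source tag and the raw pKa measurement(s) attached to the
SDF record (or activity-table row) it came from.  Identity throughout the
package is the canonical isomeric SMILES string.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

SOURCE_TAGS = ("chembl", "datawarrior", "novartis", "literature", "user")

#: SDF property keys probed for a pKa value, in order.  The public data
#: sources label the value differently, so the list is configurable per call.
DEFAULT_PKA_PROPERTY_NAMES = (
    "pKa", "pka", "PKA", "pKa value", "basicOrAcidic pKa", "Standard Value",
)

#: Allowed ``standard_type`` labels for activity-table filtering
#: (matched case-insensitively).
PKA_STANDARD_TYPES = frozenset(
    {"pka", "pka value", "pka1", "pka2", "pka3", "pka4"}
)


@dataclass
class PkaMeasurement:
    """A single experimental pKa value with its annotations.

    Parameters
    ----------
    value
        The pKa in log units; must be finite.
    relation
        Comparator string, e.g. ``"="`` for an exact measurement.
    type_label
        Free-text type annotation, e.g. ``"pKa1"``.
    method_label
        Optional experimental method, e.g. ``"potentiometric"`` or
        ``"capillary electrophoresis"``.
    """

    value: float
    relation: str = "="
    type_label: str = "pKa"
    method_label: str | None = None

    def __post_init__(self) -> None:
        self.value = float(self.value)
        if not math.isfinite(self.value):
            raise ValueError(f"pKa measurement must be finite, got {self.value}")


@dataclass
class MoleculeRecord:
    """One structure as read from file, with source tag and raw measurements."""

    mol: Chem.Mol
    source_tag: str = "user"
    measurements: list[PkaMeasurement] = field(default_factory=list)
    record_name: str = ""

    @property
    def smiles(self) -> str:
        return canonical_isomeric_smiles(self.mol)


@dataclass
class CuratedEntry:
    """A unique curated molecule with its aggregated pKa.

    ``pka`` is the arithmetic mean of the measurements retained after
    outlier removal, so it always lies within their [min, max].
    """

    canonical_smiles: str
    pka: float
    n_used: int = 1
    n_removed: int = 0
    sources: frozenset[str] = frozenset()
    mol: Chem.Mol | None = None

    def __post_init__(self) -> None:
        if self.n_used < 1:
            raise ValueError("a curated entry must retain at least one measurement")
        if self.mol is None:
            self.mol = Chem.MolFromSmiles(self.canonical_smiles)
        if self.mol is None:
            raise ValueError(f"unparseable canonical SMILES {self.canonical_smiles!r}")


def canonical_isomeric_smiles(mol: Chem.Mol) -> str:
    """Canonical isomeric SMILES of ``mol`` — the package's identity key.

    Deterministic, invariant to input atom ordering, stereo-preserving.
    """
    if mol is None:
        raise ValueError("cannot canonicalize None")
    return Chem.MolToSmiles(mol, isomericSmiles=True)


def smiles_to_mol(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising ``ValueError`` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    return mol


def _parse_pka_property(raw: str) -> float | None:
    try:
        value = float(str(raw).strip())
    except (TypeError, ValueError):
        return None
    return value if math.isfinite(value) else None


def read_sdf(
    path,
    source_tag: str = "user",
    pka_property_names=DEFAULT_PKA_PROPERTY_NAMES,
    method_property: str = "method",
) -> tuple[list[MoleculeRecord], int]:
    """Read an SDF file into :class:`MoleculeRecord` objects.

    Records whose connection table fails to parse or sanitize are skipped
    and counted, never fatal.  Each named property that parses as a finite
    number becomes one :class:`PkaMeasurement`; a non-numeric value under a
    pKa key is dropped with a log message rather than coerced.

    Returns
    -------
    (records, n_skipped)
    """
    import os
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such SDF file: {path}")
    if os.path.getsize(path) == 0:  # a valid write_sdf([]) product
        return [], 0
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    records: list[MoleculeRecord] = []
    n_skipped = 0
    for i, mol in enumerate(supplier):
        if mol is None:
            n_skipped += 1
            logger.info("skipping unparseable record %d in %s", i, path)
            continue
        measurements = []
        method = mol.GetProp(method_property) if mol.HasProp(method_property) else None
        for key in pka_property_names:
            if not mol.HasProp(key):
                continue
            value = _parse_pka_property(mol.GetProp(key))
            if value is None:
                logger.info(
                    "record %d in %s: property %r=%r is not a finite number; dropped",
                    i, path, key, mol.GetProp(key),
                )
                continue
            measurements.append(
                PkaMeasurement(value=value, type_label=key, method_label=method)
            )
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"record_{i}"
        records.append(
            MoleculeRecord(mol=mol, source_tag=source_tag,
                           measurements=measurements, record_name=name)
        )
    return records, n_skipped


def write_sdf(items, path, extra_properties: dict | None = None,
              pka_property: str = "pKa") -> int:
    """Write records or curated entries to an SDF file; returns the count.

    The output round-trips through :func:`read_sdf` with identical canonical
    SMILES and property values to printed precision.
    """
    writer = Chem.SDWriter(str(path))
    n = 0
    try:
        for item in items:
            if isinstance(item, CuratedEntry):
                mol = Chem.Mol(item.mol)
                mol.SetProp("_Name", item.canonical_smiles)
                mol.SetProp(pka_property, f"{item.pka:.6g}")
                mol.SetProp("n_used", str(item.n_used))
                mol.SetProp("n_removed", str(item.n_removed))
                if item.sources:
                    mol.SetProp("sources", ",".join(sorted(item.sources)))
            else:
                mol = Chem.Mol(item.mol)
                mol.SetProp("_Name", item.record_name or "")
                if item.measurements:
                    mol.SetProp(pka_property, f"{item.measurements[0].value:.6g}")
            for key, val in (extra_properties or {}).items():
                mol.SetProp(str(key), str(val))
            writer.write(mol)
            n += 1
    finally:
        writer.close()
    return n


def filter_activity_table(
    rows: pd.DataFrame,
    relation_col: str = "standard_relation",
    type_col: str = "standard_type",
    value_col: str = "standard_value",
    structure_col: str = "canonical_smiles",
) -> list[tuple[str, PkaMeasurement]]:
    """Apply the activity-export filtering rules to a table of assay rows.

    A row is kept only if its relation is exactly ``"="`` (after whitespace
    strip), its type is one of the allowed pKa labels case-insensitively,
    its value parses as a finite number, and a structure is present.
    Rows lacking a structure are dropped, mirroring how measurements
    without an available molecular structure are sorted out at the source.
    """
    for col in (relation_col, type_col, value_col, structure_col):
        if col not in rows.columns:
            raise KeyError(f"activity table is missing required column {col!r}")
    kept: list[tuple[str, PkaMeasurement]] = []
    for _, row in rows.iterrows():
        structure = row[structure_col]
        if pd.isna(structure) or not str(structure).strip():
            continue
        relation = str(row[relation_col]).strip()
        if relation != "=":
            continue
        type_label = str(row[type_col]).strip()
        if type_label.lower() not in PKA_STANDARD_TYPES:
            continue
        value = _parse_pka_property(row[value_col])
        if value is None:
            continue
        kept.append(
            (str(structure).strip(),
             PkaMeasurement(value=value, relation=relation, type_label=type_label))
        )
    return kept
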