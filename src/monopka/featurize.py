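"""Molecular featurization: whole-molecule descriptors, Morgan feature
fingerprints, z-scaling, and the dataset-characterization primitives
(Murcko scaffolds, cross-set Tanimoto similarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

from ._descriptor_names import DESCRIPTOR_NAMES
from .chem_io import CuratedEntry

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)  # 196
FP_BITS = 4096
FP_RADIUS = 3

#: The six feature configurations of the benchmark grid.
FEATURE_CONFIGS = ("desc", "fp", "desc+fp",
                   "desc_scaled", "fp_scaled", "desc+fp_scaled")

_DESC_FUNCS = {name: func for name, func in Descriptors.descList}


def compute_descriptors(mol: Chem.Mol) -> np.ndarray:
    """The frozen 196-descriptor vector for one molecule.

    The four partial-charge descriptors are excluded (NaN for many
    molecules); any residual non-finite value raises, flagging the molecule
    for exclusion rather than propagating NaN into a model.
    """
    values = np.empty(N_DESCRIPTORS)
    for j, name in enumerate(DESCRIPTOR_NAMES):
        values[j] = _DESC_FUNCS[name](mol)
    if not np.all(np.isfinite(values)):
        bad = [DESCRIPTOR_NAMES[j] for j in np.flatnonzero(~np.isfinite(values))]
        raise ValueError(f"non-finite descriptors {bad} for "
                         f"{Chem.MolToSmiles(mol)}")
    return values


_FP_GENERATOR = rdFingerprintGenerator.GetMorganGenerator(
    radius=FP_RADIUS, fpSize=FP_BITS,
    atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
)


def feature_morgan_fingerprint(mol: Chem.Mol, radius: int = FP_RADIUS,
                               nbits: int = FP_BITS) -> np.ndarray:
    """Binary Morgan feature fingerprint (pharmacophoric invariants).

    Defaults: radius 3 folded to 4096 bits (an FCFP6-like fingerprint).
    """
    if mol is None:
        raise ValueError("cannot fingerprint None")
    if radius == FP_RADIUS and nbits == FP_BITS:
        fp = _FP_GENERATOR.GetFingerprint(mol)
    else:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits,
            atomInvariantsGenerator=rdFingerprintGenerator.GetMorganFeatureAtomInvGen(),
        )
        fp = gen.GetFingerprint(mol)
    arr = np.zeros(nbits, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr


@dataclass
class ScalingState:
    """Per-column centering/scaling statistics learned from training rows only."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, block: np.ndarray) -> np.ndarray:
        sd = np.where(self.sd == 0.0, 1.0, self.sd)  # constant cols: centre only
        return (block - self.mean) / sd


def z_transform(matrix: np.ndarray, train_mask: np.ndarray
                ) -> tuple[np.ndarray, ScalingState]:
    """Standardize columns using statistics from the training rows only.

    Columns with zero training SD are centred but not divided, so a
    constant column maps to all zeros.  Held-out rows are transformed with
    the training statistics and never influence them.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    if not train_mask.any():
        raise ValueError("training mask selects no rows")
    train = matrix[train_mask]
    state = ScalingState(mean=train.mean(axis=0), sd=train.std(axis=0))
    return state.apply(matrix), state


@dataclass
class FeatureMatrix:
    """Descriptor and fingerprint blocks for a list of molecules.

    The descriptor block is n x 196 (frozen column order), the fingerprint
    block n x 4096 binary.  ``get(config)`` serves any of the six benchmark
    configurations; scaled variants fit their statistics on ``train_mask``
    rows (default: all rows are training rows).
    """

    smiles: list[str]
    descriptors: np.ndarray
    fingerprints: np.ndarray
    scaling: dict[str, ScalingState] = field(default_factory=dict)

    @classmethod
    def from_entries(cls, entries: list[CuratedEntry]) -> "FeatureMatrix":
        smiles, desc_rows, fp_rows = [], [], []
        for e in entries:
            desc_rows.append(compute_descriptors(e.mol))
            fp_rows.append(feature_morgan_fingerprint(e.mol))
            smiles.append(e.canonical_smiles)
        return cls(smiles=smiles,
                   descriptors=np.asarray(desc_rows, dtype=np.float64),
                   fingerprints=np.asarray(fp_rows, dtype=np.float64))

    @classmethod
    def from_mols(cls, mols: list[Chem.Mol]) -> "FeatureMatrix":
        smiles = [Chem.MolToSmiles(m) for m in mols]
        desc = np.asarray([compute_descriptors(m) for m in mols], dtype=np.float64)
        fps = np.asarray([feature_morgan_fingerprint(m) for m in mols],
                         dtype=np.float64)
        return cls(smiles=smiles, descriptors=desc, fingerprints=fps)

    def __len__(self) -> int:
        return len(self.smiles)

    def get(self, config: str, train_mask: np.ndarray | None = None) -> np.ndarray:
        """Feature block for one of the six configurations.

        For scaled configurations the scaling state is learned on
        ``train_mask`` rows (all rows if omitted), cached, and reused.
        """
        if config not in FEATURE_CONFIGS:
            raise ValueError(f"unknown feature configuration {config!r}; "
                             f"expected one of {FEATURE_CONFIGS}")
        base = config.removesuffix("_scaled")
        raw = {"desc": self.descriptors,
               "fp": self.fingerprints,
               "desc+fp": np.hstack([self.descriptors, self.fingerprints])}[base]
        if not config.endswith("_scaled"):
            return raw
        if config not in self.scaling:
            mask = (np.ones(len(self), dtype=bool)
                    if train_mask is None else train_mask)
            scaled, state = z_transform(raw, mask)
            self.scaling[config] = state
            return scaled
        return self.scaling[config].apply(raw)

    def transform_like(self, other_config: str, block_source: "FeatureMatrix"
                       ) -> np.ndarray:
        """Serve this matrix's rows using scaling learned by another matrix."""
        base = other_config.removesuffix("_scaled")
        raw = {"desc": self.descriptors,
               "fp": self.fingerprints,
               "desc+fp": np.hstack([self.descriptors, self.fingerprints])}[base]
        if not other_config.endswith("_scaled"):
            return raw
        state = block_source.scaling.get(other_config)
        if state is None:
            raise ValueError(f"source matrix has no scaling state for "
                             f"{other_config!r}; call get() on it first")
        return state.apply(raw)


def murcko_scaffold(mol: Chem.Mol) -> str:
    """Canonical Murcko scaffold SMILES; acyclic molecules map to ''."""
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a & b| / |a | b| of two binary vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def cross_set_similarities(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """For each fingerprint in A, its maximum Tanimoto similarity over B.

    Vectorized popcount arithmetic: works on {0,1} matrices of any width.
    """
    A = np.asarray(fps_a, dtype=np.float64)
    B = np.asarray(fps_b, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] == 0 or B.shape[0] == 0:
        raise ValueError("both fingerprint sets must be non-empty 2-D arrays")
    inter = A @ B.T
    pop_a = A.sum(axis=1)[:, None]
    pop_b = B.sum(axis=1)[None, :]
    union = pop_a + pop_b - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    return sim.max(axis=1)
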