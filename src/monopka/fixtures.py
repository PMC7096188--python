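"""Programmatic generation of small, fully-characterized test inputs.

Two generators live here:

* :func:`generate_curation_fixture` emits an SDF of real, hand-curated
  drug-like structures decorated so that each record has a *known* fate at
  a known curation stage (salt stripped, nitro dropped, out-of-window
  dropped, ...), together with a manifest stating those fates.  The
  manifest is the oracle for pipeline tests: it is computed entirely by
  construction and never by running the curation code itself.

* :func:`generate_regression_fixture` builds a diverse set of synthetic
  molecules whose "experimental" pKa is a known sparse affine function of
  their own descriptors plus Gaussian noise, for parameter-recovery tests
  of the learning machinery.

Base structures are real, chemically sane molecules (phenols, pyridines,
anilines, ...) chosen to be fixed points of the default tautomer
canonicalizer and pH-7.4 protonation rules, so their canonical SMILES
survives standardization unchanged and the manifests stay exact.
Annotated pKa values are textbook-scale class values; they only need to be
chemically plausible, not accurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem_io import CuratedEntry

#: Clean base molecules: single fragment, no forbidden element or nitro
#: group, at most one Lipinski violation, canonical-SMILES-stable under the
#: default standardization.  (canonical SMILES, plausible pKa).
CLEAN_MOLECULES: tuple[tuple[str, float], ...] = (
    ("Oc1ccccc1", 9.99), ("Cc1ccc(O)cc1", 10.3), ("Oc1ccc(Cl)cc1", 9.4),
    ("COc1ccccc1O", 9.9), ("Oc1ccc(F)cc1", 9.9), ("Cc1cccc(O)c1", 10.1),
    ("Oc1ccc(Br)cc1", 9.3), ("CC(C)c1ccc(O)cc1", 10.2), ("Oc1ccc(I)cc1", 9.3),
    ("Cc1ccccc1O", 10.3), ("CCc1ccc(O)cc1", 10.0), ("COc1ccc(O)cc1", 10.2),
    ("c1ccncc1", 5.2), ("Cc1cccnc1", 5.6), ("Cc1ccncc1", 6.0),
    ("c1ccc2ncccc2c1", 4.9), ("c1ccc2cnccc2c1", 5.4), ("Cc1ccccn1", 5.9),
    ("CCc1ccccn1", 5.9), ("Clc1ccncc1", 3.8), ("Brc1cccnc1", 2.8),
    ("Nc1ccccc1", 4.6), ("Cc1ccc(N)cc1", 5.1), ("Nc1ccc(Cl)cc1", 4.0),
    ("COc1ccc(N)cc1", 5.3), ("Cc1cccc(N)c1", 4.7), ("CCNc1ccccc1", 5.1),
    ("Nc1ccc(Br)cc1", 3.9), ("Nc1ccc(F)cc1", 4.7), ("CN(C)c1ccccc1", 5.1),
    ("Oc1ccc2ccccc2c1", 9.5), ("Oc1cccc2ccccc12", 9.4),
    ("Nc1ccc2ccccc2c1", 4.3), ("c1ccc(-c2ccncc2)cc1", 5.5),
    ("CCCCCCCCCCCCCCCC", 7.0), ("c1ccc(Cc2ccncc2)cc1", 5.9),
    ("CCc1ccc(O)c(C)c1", 10.2), ("Cn1ccnc1", 7.0),
    ("c1cnc2[nH]ccc2c1", 4.9), ("NS(=O)(=O)c1ccccc1", 10.0),
    ("Clc1ccccn1", 2.5), ("CC(C)(C)c1ccc(O)cc1", 10.2),
)

#: Counter-ion fragments appended to make salt records.
COUNTER_IONS = ("[Na+]", "Cl", "[K+]", "Br", "O=S(=O)(O)O")

#: Structures dropped at the element/nitro stage.
NITRO_MOLECULES = ("O=[N+]([O-])c1ccccc1", "Cc1ccc(cc1)[N+](=O)[O-]",
                   "O=[N+]([O-])c1ccc(O)cc1")
ELEMENT_MOLECULES = ("CCB(CC)CC", "C[Se]CCC(N)C(=O)O", "C[Si](C)(C)C")

#: >=2 Lipinski violations (long alkanes: MW > 500 and logP > 5).
LIPINSKI_VIOLATORS = ("C" * 40, "C" * 44, "C" * 48)

#: No organic fragment at all: dropped at salt stripping.
INORGANIC = ("[Na+].[Cl-]", "[K+].[Br-]")


@dataclass
class FixtureSpec:
    """Recipe for a curation fixture.

    ``n`` records are drawn; the fraction fields say how many are
    engineered to trip each stage (the remainder are clean survivors,
    some emitted as replicate groups with Gaussian noise of
    ``replicate_noise_sd`` and, at ``outlier_rate``, one extra value
    displaced by ``outlier_magnitude`` for the 2-SD merge rule to remove).
    """

    n: int = 40
    frac_salt: float = 0.1          # salt-stripped but surviving
    frac_inorganic: float = 0.05    # dropped: no organic fragment
    frac_nitro_element: float = 0.1
    frac_lipinski: float = 0.05
    frac_window: float = 0.1        # pKa outside [2, 12]
    frac_multiprotic: float = 0.1   # stub predictor reports two values
    frac_pred_outlier: float = 0.05
    replicate_groups: int = 3
    replicates_per_group: int = 4
    replicate_noise_sd: float = 0.05
    outlier_rate: float = 1.0       # fraction of replicate groups given an outlier
    outlier_magnitude: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = (self.frac_salt + self.frac_inorganic + self.frac_nitro_element
                 + self.frac_lipinski + self.frac_window + self.frac_multiprotic
                 + self.frac_pred_outlier)
        if total > 1.0 + 1e-9:
            raise ValueError(f"category fractions sum to {total:.3f} > 1")


class StubPredictor:
    """Deterministic lookup predictor for tests: canonical SMILES -> values.

    Satisfies the external-predictor contract; only in-window values are
    returned.
    """

    def __init__(self, table: dict[str, list[float]]):
        self.table = {k: list(v) for k, v in table.items()}

    def predict_in_window(self, mol: Chem.Mol, lo: float, hi: float) -> list[float]:
        key = Chem.MolToSmiles(mol)
        return [v for v in self.table.get(key, []) if lo <= v <= hi]


@dataclass
class CurationFixture:
    """A generated fixture: the SDF path, its manifest, and the stub predictor.

    Manifest columns: ``record_id``, ``smiles`` (as written), ``base_smiles``
    (canonical clean form), ``category``, ``pka``, ``expected_fate`` (either
    ``survive`` or the curation stage expected to drop the record),
    ``group_id`` (replicate group, or -1) and ``expected_pka`` /
    ``expected_n_used`` for surviving groups.
    """

    sdf_path: Path
    manifest: pd.DataFrame
    predictor: StubPredictor
    spec: FixtureSpec

    @property
    def expected_survivors(self) -> pd.DataFrame:
        """One row per expected curated entry (keyed by base_smiles)."""
        surv = self.manifest[self.manifest.expected_fate == "survive"]
        return (surv.groupby("base_smiles")
                .agg(expected_pka=("expected_pka", "first"),
                     expected_n_used=("expected_n_used", "first"))
                .reset_index())


def generate_curation_fixture(spec: FixtureSpec, sdf_path) -> CurationFixture:
    """Write a fixture SDF and its expected-outcome manifest.

    Deterministic: the seed fully determines the byte content of the SDF.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    counts = {
        "salt": round(spec.frac_salt * n),
        "inorganic": round(spec.frac_inorganic * n),
        "nitro_element": round(spec.frac_nitro_element * n),
        "lipinski": round(spec.frac_lipinski * n),
        "window": round(spec.frac_window * n),
        "multiprotic": round(spec.frac_multiprotic * n),
        "pred_outlier": round(spec.frac_pred_outlier * n),
    }
    n_special = sum(counts.values())
    n_replicate_records = spec.replicate_groups * spec.replicates_per_group
    n_clean = n - n_special - n_replicate_records
    if n_clean < 0:
        raise ValueError("spec infeasible: special + replicate records exceed n")

    # Deal distinct clean base molecules to the roles that need them, so no
    # curated-entry group mixes two roles.
    pool = list(CLEAN_MOLECULES)
    need = (counts["salt"] + counts["window"] + counts["multiprotic"]
            + counts["pred_outlier"] + spec.replicate_groups + n_clean)
    if need > len(pool):
        raise ValueError(
            f"spec needs {need} distinct base molecules, only {len(pool)} available")
    order = rng.permutation(len(pool))
    picked = [pool[i] for i in order]

    def take(k):
        nonlocal picked
        out, picked = picked[:k], picked[k:]
        return out

    rows = []          # manifest rows
    stub_table = {}    # canonical SMILES -> predicted values

    def add(smiles, base_smiles, category, pka, fate, group_id=-1,
            expected_pka=np.nan, expected_n_used=0):
        rows.append(dict(record_id=len(rows), smiles=smiles,
                         base_smiles=base_smiles, category=category,
                         pka=float(pka), expected_fate=fate, group_id=group_id,
                         expected_pka=expected_pka,
                         expected_n_used=expected_n_used))

    for base, pka in take(counts["salt"]):
        ion = COUNTER_IONS[len(rows) % len(COUNTER_IONS)]
        stub_table[base] = [pka]
        add(f"{base}.{ion}", base, "salt", pka, "survive",
            expected_pka=pka, expected_n_used=1)
    for i in range(counts["inorganic"]):
        smi = INORGANIC[i % len(INORGANIC)]
        add(smi, smi, "inorganic", 7.0, "strip_salts")
    for i in range(counts["nitro_element"]):
        bank = NITRO_MOLECULES + ELEMENT_MOLECULES
        smi = bank[i % len(bank)]
        add(smi, smi, "nitro_element", 7.0, "element_group_filter")
    for i in range(counts["lipinski"]):
        smi = LIPINSKI_VIOLATORS[i % len(LIPINSKI_VIOLATORS)]
        add(smi, smi, "lipinski", 7.0, "lipinski_filter")
    for base, _ in take(counts["window"]):
        out_value = 1.0 if len(rows) % 2 == 0 else 13.0
        add(base, base, "window", out_value, "pka_window")
    for base, pka in take(counts["multiprotic"]):
        stub_table[base] = [4.0, 9.5]
        add(base, base, "multiprotic", pka, "monoprotic")
    for base, pka in take(counts["pred_outlier"]):
        stub_table[base] = [pka]
        recorded = pka + 5.0 if pka + 5.0 <= 12.0 else pka - 5.0
        add(base, base, "pred_outlier", recorded, "prediction_outliers")
    for g, (base, pka) in enumerate(take(spec.replicate_groups)):
        stub_table[base] = [pka]
        # values are rounded to the SDF's printed precision so the manifest's
        # expected mean matches what the pipeline reads back; the outlier sign
        # is chosen to keep it inside the pKa window
        values = [round(v, 4) for v in
                  pka + rng.normal(0.0, spec.replicate_noise_sd,
                                   spec.replicates_per_group)]
        has_outlier = rng.random() < spec.outlier_rate
        if has_outlier:
            sign = 1.0 if pka + spec.outlier_magnitude <= 12.0 else -1.0
            values.append(round(pka + sign * spec.outlier_magnitude, 4))
        # expected merge outcome, by the fixture's own arithmetic
        arr = np.asarray(values)
        mean, sd = arr.mean(), arr.std()
        kept = arr[np.abs(arr - mean) <= 2.0 * sd] if len(arr) > 2 else arr
        for v in values:
            add(base, base, "replicate", v, "survive", group_id=g,
                expected_pka=float(kept.mean()), expected_n_used=len(kept))
    for base, pka in take(n_clean):
        stub_table[base] = [pka]
        add(base, base, "clean", pka, "survive",
            expected_pka=pka, expected_n_used=1)

    manifest = pd.DataFrame(rows)
    sdf_path = Path(sdf_path)
    writer = Chem.SDWriter(str(sdf_path))
    try:
        for row in rows:
            mol = Chem.MolFromSmiles(row["smiles"])
            if mol is None:  # pragma: no cover - all fixture SMILES are valid
                raise ValueError(f"fixture SMILES failed to parse: {row['smiles']}")
            mol.SetProp("_Name", f"fixture_{row['record_id']}")
            mol.SetProp("pKa", f"{row['pka']:.4f}")
            writer.write(mol)
    finally:
        writer.close()
    return CurationFixture(sdf_path=sdf_path, manifest=manifest,
                           predictor=StubPredictor(stub_table), spec=spec)


# ---------------------------------------------------------------------------
# regression fixture
# ---------------------------------------------------------------------------

_CORE_TEMPLATES = (
    "{a}c1ccc({b})cc1", "{a}c1ccc({b})cn1", "{a}c1ccc({b})nc1",
    "{a}C1CCC({b})CC1", "{a}c1ccc2cc({b})ccc2c1", "{a}c1cc({b})ccc1C",
    "{a}C1CCN({b})CC1", "{a}c1ccc({b})o1", "{a}c1ccc({b})s1",
    "{a}c1cnc({b})cn1",
)
_SUBSTITUENTS = (
    "C", "CC", "CCC", "CCCC", "CC(C)C", "CCO", "CCCO", "COC", "CCN(C)C",
    "CCl", "CBr", "CF", "CC(F)(F)F", "CCOC", "CC=C", "CC#N", "CCS",
    "CCCN", "CC(C)O", "CCCCC", "C(C)(C)C", "CCCCl", "COCC", "CC(C)CC",
)

#: Descriptor pool from which the generator's sparse weights are drawn.
GENERATOR_DESCRIPTORS = ("MolWt", "MolLogP", "TPSA", "NumRotatableBonds",
                         "NumHDonors", "RingCount")


@dataclass
class GeneratorRecord:
    """Ground truth of a regression fixture, for recovery tests."""

    descriptor_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    column_means: np.ndarray
    column_sds: np.ndarray
    noise_sd: float
    seed: int
    clip: tuple[float, float] = (2.0, 12.0)


def _diverse_molecules(n: int, rng: np.random.Generator) -> list[Chem.Mol]:
    """Sample n unique, valid molecules from the template grammar."""
    mols, seen = [], set()
    templates = list(_CORE_TEMPLATES)
    subs = list(_SUBSTITUENTS)
    attempts = 0
    while len(mols) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("molecule grammar exhausted before reaching n")
        t = templates[int(rng.integers(len(templates)))]
        a = subs[int(rng.integers(len(subs)))]
        b = subs[int(rng.integers(len(subs)))]
        smi = t.format(a=a, b=b)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        mols.append(Chem.MolFromSmiles(can))
    return mols


def generate_regression_fixture(
    n: int = 1000,
    n_active: int = 3,
    noise_sd: float = 0.3,
    seed: int = 0,
    signal_sd: float = 2.0,
    center: float = 7.0,
) -> tuple[list[CuratedEntry], GeneratorRecord]:
    """Entries whose pKa is a known sparse function of their descriptors.

    The synthetic pKa is ``center + w . z(d) + eps`` clipped to [2, 12],
    where ``d`` is an ``n_active``-subset of simple descriptors standardized
    over the generated set, the weights are scaled so the noise-free signal
    has SD ``signal_sd``, and ``eps`` is Gaussian with SD ``noise_sd``
    (default 0.3 log units, the scale of inter-source measurement scatter).
    """
    if n < 50:
        raise ValueError("regression fixture needs n >= 50")
    if not 1 <= n_active <= len(GENERATOR_DESCRIPTORS):
        raise ValueError(f"n_active must be in [1, {len(GENERATOR_DESCRIPTORS)}]")
    from rdkit.Chem import Descriptors
    rng = np.random.default_rng(seed)
    mols = _diverse_molecules(n, rng)
    chosen = tuple(sorted(rng.choice(len(GENERATOR_DESCRIPTORS), size=n_active,
                                     replace=False)))
    names = tuple(GENERATOR_DESCRIPTORS[i] for i in chosen)
    funcs = [getattr(Descriptors, name) for name in names]
    D = np.array([[f(m) for f in funcs] for m in mols])
    means, sds = D.mean(axis=0), D.std(axis=0)
    sds = np.where(sds == 0.0, 1.0, sds)
    Z = (D - means) / sds
    raw_w = rng.uniform(0.5, 1.5, size=n_active) * rng.choice([-1.0, 1.0],
                                                              size=n_active)
    signal = Z @ raw_w
    scale = signal_sd / max(signal.std(), 1e-12)
    weights = raw_w * scale
    y = center + signal * scale + rng.normal(0.0, noise_sd, size=n)
    y = np.clip(y, 2.0, 12.0)
    entries = [CuratedEntry(canonical_smiles=Chem.MolToSmiles(m), pka=float(v),
                            sources=frozenset({"user"}), mol=m)
               for m, v in zip(mols, y)]
    record = GeneratorRecord(descriptor_names=names, weights=weights,
                             intercept=center, column_means=means,
                             column_sds=sds, noise_sd=noise_sd, seed=seed)
    return entries, record
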