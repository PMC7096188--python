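"""The eight-step curation pipeline that turns raw pKa records into unique
monoprotic training entries.

Stages, applied in order:

1. salt stripping (keep the largest organic fragment),
2. removal of structures containing nitro groups or B/Se/Si,
3. Lipinski rule-of-five filter (one violation allowed),
4. pKa window filter (keep measurements with 2 <= pKa <= 12, inclusive),
5. tautomer standardization,
6. protonation at pH 7.4,
7. monoprotic filter (at most one predicted pKa inside the window),
8. outlier removal and duplicate merging: first drop measurements whose
   predicted pKa deviates from experiment by more than four log units, then
   group by canonical isomeric SMILES, drop values more than two standard
   deviations from the group mean (single pass, population SD), and average
   the survivors.

Steps 5-7 historically relied on proprietary engines; here they are
pluggable adapters with open rule-based defaults, so absolute counts on the
public datasets differ from runs using the original tools, but the pipeline
semantics and every threshold are identical.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Callable, Protocol

from rdkit import Chem
from rdkit.Chem import Descriptors, Lipinski
from rdkit.Chem.Descriptors import MolWt
from rdkit.Chem.MolStandardize import rdMolStandardize

from .chem_io import CuratedEntry, MoleculeRecord, canonical_isomeric_smiles

logger = logging.getLogger(__name__)


@dataclass
class CurationConfig:
    """Thresholds of the curation pipeline.

    Defaults are the published protocol: pKa window [2, 12], one Lipinski
    violation allowed, a 4-log-unit cut against the reference predictor,
    a 2-SD cut inside duplicate groups, protonation at pH 7.4, and B/Se/Si
    as forbidden elements.
    """

    pka_min: float = 2.0
    pka_max: float = 12.0
    lipinski_max_violations: int = 1
    prediction_deviation_cut: float = 4.0
    sd_multiplier: float = 2.0
    ph_for_protonation: float = 7.4
    forbidden_elements: frozenset[str] = frozenset({"B", "Se", "Si"})

    def __post_init__(self) -> None:
        if not self.pka_min < self.pka_max:
            raise ValueError("pka_min must be below pka_max")
        for name in ("prediction_deviation_cut", "sd_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class ExternalPkaPredictor(Protocol):
    """Contract for the reference pKa predictor used by stages 7 and 8.

    ``predict_in_window(mol, lo, hi)`` returns the predicted pKa values of
    ``mol`` that fall inside ``[lo, hi]``; it must be deterministic per
    structure and return only in-window values.
    """

    def predict_in_window(self, mol: Chem.Mol, lo: float, hi: float) -> list[float]:
        ...


# SMARTS rules mapping an ionizable substructure to a crude macroscopic pKa.
# Charged depictions are listed alongside neutral ones so the rules keep
# working after the pH-7.4 protonation stage.  Values are textbook medians
# for the group class; they only need to be right to within the four-log-unit
# deviation cut, not quantitative.
_IONIZABLE_RULES: tuple[tuple[str, float], ...] = (
    ("[CX3](=O)[OX2H1]", 4.0),               # carboxylic acid
    ("[CX3](=O)[OX1-]", 4.0),                # carboxylate
    ("[c][OX2H1]", 9.9),                      # phenol
    ("[c][OX1-]", 9.9),                       # phenolate
    ("[SX4](=O)(=O)[NX3;H1,H2]", 10.0),       # sulfonamide N-H
    ("[NX3;+0;H2,H1,H0;!$(N~[!#6;!#1]);!$(N-[CX3]=[O,S,N]);!$(N-c);!$(N=*);!$(N#*)]", 10.5),
    ("[NX4;+1;!$(N-c)]", 10.5),               # aliphatic amine / ammonium
    ("[NX3;+0;$(N-c);H2,H1]", 4.6),           # aniline
    ("n1ccccc1", 5.2),                         # pyridine
    ("c1nc[nH]c1", 7.0),                       # imidazole
    ("[NX2;+0]=[CX3][NX3;+0]", 11.5),         # amidine / amidinium system
    ("c1nnn[nH]1", 4.9),                       # tetrazole
)


class RuleBasedPkaPredictor:
    """Open default reference predictor: a SMARTS ionizable-site estimator.

    Each matched ionizable group contributes one predicted macroscopic pKa
    (its class median).  This is a coarse stand-in for a quantitative
    predictor — sufficient for counting ionization events in a window and
    for the four-log-unit sanity cut, not for accurate prediction.
    """

    def __init__(self) -> None:
        self._patterns = [
            (Chem.MolFromSmarts(smarts), pka) for smarts, pka in _IONIZABLE_RULES
        ]

    def predict_in_window(self, mol: Chem.Mol, lo: float, hi: float) -> list[float]:
        seen_atoms: set[int] = set()
        values: list[float] = []
        for pattern, pka in self._patterns:
            for match in mol.GetSubstructMatches(pattern):
                # one pKa per ionizable centre: skip groups whose atoms were
                # already claimed by an earlier (more specific) rule
                if seen_atoms.intersection(match):
                    continue
                seen_atoms.update(match)
                if lo <= pka <= hi:
                    values.append(pka)
        return values


class LookupPkaPredictor:
    """Predictor backed by a fixed canonical-SMILES -> values table.

    Used to stand in for an external engine in tests and to replay cached
    predictions from a file.
    """

    def __init__(self, table: dict[str, list[float]]):
        self.table = dict(table)

    def predict_in_window(self, mol: Chem.Mol, lo: float, hi: float) -> list[float]:
        key = canonical_isomeric_smiles(mol)
        return [v for v in self.table.get(key, []) if lo <= v <= hi]


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def strip_salts(mol: Chem.Mol) -> Chem.Mol | None:
    """Keep the largest organic fragment; ``None`` signals an all-inorganic drop.

    Largest by heavy-atom count, ties broken by molecular weight then by
    canonical SMILES order.  Single-fragment input is returned unchanged.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    organic = [f for f in frags
               if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        return None
    return max(
        organic,
        key=lambda f: (f.GetNumHeavyAtoms(), MolWt(f),
                       canonical_isomeric_smiles(f)),
    )


_NITRO_PATTERNS = (
    Chem.MolFromSmarts("[NX3](=O)[O-]"),       # charge-separated depiction
    Chem.MolFromSmarts("[NX3](=O)=O"),          # neutral pentavalent depiction
)


def element_and_group_filter(
    mol: Chem.Mol, config: CurationConfig
) -> tuple[bool, str | None]:
    """Drop structures containing a nitro group or a forbidden element.

    Returns ``(keep, reason)``; ``reason`` names the offending rule.
    """
    for atom in mol.GetAtoms():
        if atom.GetSymbol() in config.forbidden_elements:
            return False, f"element {atom.GetSymbol()}"
    for pattern in _NITRO_PATTERNS:
        if mol.HasSubstructMatch(pattern):
            return False, "nitro"
    return True, None


def lipinski_violations(mol: Chem.Mol) -> int:
    """Count rule-of-five violations: MW>500, logP>5, HBD>5, HBA>10.

    Classic definitions: donors = N-H/O-H count, acceptors = N+O count,
    logP = the atom-contribution (Crippen) estimate.
    """
    violations = 0
    if Descriptors.MolWt(mol) > 500:
        violations += 1
    if Descriptors.MolLogP(mol) > 5:
        violations += 1
    if Lipinski.NumHDonors(mol) > 5:
        violations += 1
    if Lipinski.NumHAcceptors(mol) > 10:
        violations += 1
    return violations


def lipinski_filter(mol: Chem.Mol, config: CurationConfig) -> tuple[bool, int]:
    """Keep iff the violation count does not exceed the allowance."""
    n = lipinski_violations(mol)
    return n <= config.lipinski_max_violations, n


def pka_window_filter(value: float, config: CurationConfig) -> bool:
    """Keep iff ``pka_min <= value <= pka_max`` (inclusive bounds)."""
    return config.pka_min <= value <= config.pka_max


_TAUTOMER_ENUMERATOR: rdMolStandardize.TautomerEnumerator | None = None


def standardize_tautomer(
    mol: Chem.Mol,
    adapter: Callable[[Chem.Mol], Chem.Mol] | None = None,
) -> Chem.Mol:
    """Map a molecule to its canonical tautomer.

    Idempotent.  With ``adapter`` configured its output is used verbatim;
    the open default is the toolkit's canonical-tautomer picker.
    """
    if adapter is not None:
        return adapter(mol)
    global _TAUTOMER_ENUMERATOR
    if _TAUTOMER_ENUMERATOR is None:
        _TAUTOMER_ENUMERATOR = rdMolStandardize.TautomerEnumerator()
    return _TAUTOMER_ENUMERATOR.Canonicalize(mol)


# Protonation rules applied at pH 7.4: groups whose class pKa is far from
# 7.4 get their majority protonation state.  Neutral-only SMARTS make the
# edits idempotent.
_DEPROTONATE = [Chem.MolFromSmarts(s) for s in (
    "[CX3](=O)[OX2H1]",            # carboxylic acid -> carboxylate
    "[SX4](=O)(=O)[OX2H1]",        # sulfonic acid -> sulfonate
    "[SX3](=O)[OX2H1]",            # sulfinic acid
)]
_PROTONATE_SP3_N = Chem.MolFromSmarts(
    "[NX3;+0;H2,H1,H0;!$(N~[!#6;!#1]);!$(N-[CX3]=[O,S,N]);!$(N-c);!$(N=*);!$(N#*)]"
)
_PROTONATE_IMINE_N = Chem.MolFromSmarts("[NX2;+0;$(N=[CX3]([NX3;+0])),$(N=[CX3]([NX3;+0])[NX3;+0])]")


def protonate_at_ph(
    mol: Chem.Mol,
    config: CurationConfig | None = None,
    adapter: Callable[[Chem.Mol], Chem.Mol] | None = None,
) -> Chem.Mol:
    """Assign the majority protonation state at pH 7.4.

    Open default rules: carboxylic/sulfonic/sulfinic acids are
    deprotonated; aliphatic amines and the imine nitrogen of
    amidines/guanidines are protonated.  Adapter output, when configured,
    is used verbatim.  Idempotent by construction (rules only match
    neutral depictions).
    """
    if adapter is not None:
        return adapter(mol)
    mol = Chem.RWMol(mol)
    for pattern in _DEPROTONATE:
        for match in mol.GetSubstructMatches(pattern):
            atom = mol.GetAtomWithIdx(match[-1])
            if atom.GetFormalCharge() == 0 and atom.GetTotalNumHs() >= 1:
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(0)
                atom.SetNoImplicit(True)
    for pattern, add_h in ((_PROTONATE_SP3_N, True), (_PROTONATE_IMINE_N, True)):
        for match in mol.GetSubstructMatches(pattern):
            atom = mol.GetAtomWithIdx(match[0])
            if atom.GetFormalCharge() == 0:
                atom.SetFormalCharge(+1)
                if add_h:
                    atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return out


def monoprotic_filter(
    mol: Chem.Mol, predictor: ExternalPkaPredictor, config: CurationConfig
) -> bool:
    """Keep iff the predictor reports at most one pKa inside the window.

    A molecule with zero in-window predictions is kept — the rule is the
    literal "not more than one".
    """
    values = predictor.predict_in_window(mol, config.pka_min, config.pka_max)
    return len(values) <= 1


def remove_prediction_outliers(
    entries: list[tuple[Chem.Mol, float]],
    predictor: ExternalPkaPredictor,
    config: CurationConfig,
) -> list[tuple[Chem.Mol, float]]:
    """Drop (structure, measurement) pairs far from the reference prediction.

    A pair is removed iff |predicted - experimental| strictly exceeds the
    four-log-unit cut.  Structures for which the predictor yields no
    in-window value pass through unfiltered: the rule is defined only where
    a comparison exists.
    """
    kept = []
    for mol, value in entries:
        predictions = predictor.predict_in_window(mol, config.pka_min, config.pka_max)
        if predictions and abs(predictions[0] - value) > config.prediction_deviation_cut:
            continue
        kept.append((mol, value))
    return kept


def merge_duplicates(
    groups: dict[str, list[float]],
    config: CurationConfig | None = None,
    sources: dict[str, set[str]] | None = None,
    mols: dict[str, Chem.Mol] | None = None,
) -> list[CuratedEntry]:
    """Collapse measurement groups (keyed by canonical SMILES) to one entry each.

    Single pass: the group mean and population standard deviation are
    computed once, values deviating from the mean by more than
    ``sd_multiplier`` SDs are discarded, and the survivors are arithmetically
    averaged.  Groups of size one or two skip the SD step (SD degenerate).
    Order-invariant under permutation of the values within a group.
    """
    config = config or CurationConfig()
    entries = []
    for smiles, values in groups.items():
        if not values:
            raise ValueError(f"empty measurement group for {smiles}")
        if len(values) <= 2:
            kept = list(values)
        else:
            mean = statistics.fmean(values)
            sd = statistics.pstdev(values)
            kept = [v for v in values if abs(v - mean) <= config.sd_multiplier * sd]
            assert kept, "the value nearest the mean always survives a >k*SD cut"
        entries.append(CuratedEntry(
            canonical_smiles=smiles,
            pka=statistics.fmean(kept),
            n_used=len(kept),
            n_removed=len(values) - len(kept),
            sources=frozenset(sources.get(smiles, set())) if sources else frozenset(),
            mol=mols.get(smiles) if mols else None,
        ))
    return entries


def deduplicate_test_against_train(
    test_entries: list[CuratedEntry], train_entries: list[CuratedEntry]
) -> list[CuratedEntry]:
    """Remove test entries whose canonical SMILES occurs in the training set."""
    train_keys = {e.canonical_smiles for e in train_entries}
    return [e for e in test_entries if e.canonical_smiles not in train_keys]


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class StageCount:
    stage: str
    n_in: int
    n_out: int
    drops: dict[str, str] = field(default_factory=dict)


@dataclass
class CurationReport:
    """Per-stage input/output counts and attributed drop reasons.

    Counts telescope: each stage's output count is the next stage's input
    count, and ``n_in == n_out + len(drops)`` for every filter stage.
    """

    stages: list[StageCount] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, drops: dict[str, str]) -> None:
        self.stages.append(StageCount(stage, n_in, n_out, dict(drops)))

    def as_dict(self) -> dict[str, dict]:
        return {s.stage: {"in": s.n_in, "out": s.n_out, "dropped": len(s.drops)}
                for s in self.stages}

    def __str__(self) -> str:
        lines = [f"{'stage':<22}{'in':>7}{'out':>7}{'dropped':>9}"]
        for s in self.stages:
            lines.append(f"{s.stage:<22}{s.n_in:>7}{s.n_out:>7}{len(s.drops):>9}")
        return "\n".join(lines)


def _record_key(record: MoleculeRecord) -> str:
    try:
        return record.smiles
    except Exception:
        return record.record_name or "<unparseable>"


def run_curation(
    records: list[MoleculeRecord],
    config: CurationConfig | None = None,
    predictor: ExternalPkaPredictor | None = None,
    tautomer_adapter: Callable[[Chem.Mol], Chem.Mol] | None = None,
    protonation_adapter: Callable[[Chem.Mol], Chem.Mol] | None = None,
) -> tuple[list[CuratedEntry], CurationReport]:
    """Run the full eight-stage pipeline over raw records.

    Returns the curated entries (unique by canonical isomeric SMILES) and a
    :class:`CurationReport` whose stage counts telescope.
    """
    config = config or CurationConfig()
    predictor = predictor or RuleBasedPkaPredictor()
    report = CurationReport()
    current = list(records)

    # 1. salt stripping
    out, drops = [], {}
    for rec in current:
        stripped = strip_salts(rec.mol)
        if stripped is None:
            drops[_record_key(rec)] = "no organic fragment"
            continue
        out.append(MoleculeRecord(stripped, rec.source_tag,
                                  list(rec.measurements), rec.record_name))
    report.add("strip_salts", len(current), len(out), drops)
    current = out

    # 2. forbidden elements / nitro groups
    out, drops = [], {}
    for rec in current:
        keep, reason = element_and_group_filter(rec.mol, config)
        if keep:
            out.append(rec)
        else:
            drops[_record_key(rec)] = reason
    report.add("element_group_filter", len(current), len(out), drops)
    current = out

    # 3. Lipinski (one violation allowed)
    out, drops = [], {}
    for rec in current:
        try:
            keep, n_violations = lipinski_filter(rec.mol, config)
        except Exception as exc:  # descriptor failure counts as a drop
            drops[_record_key(rec)] = f"descriptor failure: {exc}"
            continue
        if keep:
            out.append(rec)
        else:
            drops[_record_key(rec)] = f"{n_violations} Lipinski violations"
    report.add("lipinski_filter", len(current), len(out), drops)
    current = out

    # 4. pKa window on individual measurements
    out, drops = [], {}
    for rec in current:
        kept = [m for m in rec.measurements if pka_window_filter(m.value, config)]
        if kept:
            out.append(MoleculeRecord(rec.mol, rec.source_tag, kept, rec.record_name))
        else:
            drops[_record_key(rec)] = "no measurement in pKa window"
    report.add("pka_window", len(current), len(out), drops)
    current = out

    # 5. tautomer standardization
    out, drops = [], {}
    for rec in current:
        try:
            mol = standardize_tautomer(rec.mol, tautomer_adapter)
        except Exception as exc:
            drops[_record_key(rec)] = f"tautomer adapter failure: {exc}"
            continue
        out.append(MoleculeRecord(mol, rec.source_tag, rec.measurements,
                                  rec.record_name))
    report.add("tautomer", len(current), len(out), drops)
    current = out

    # 6. protonation at pH 7.4
    out, drops = [], {}
    for rec in current:
        try:
            mol = protonate_at_ph(rec.mol, config, protonation_adapter)
        except Exception as exc:
            drops[_record_key(rec)] = f"protonation adapter failure: {exc}"
            continue
        out.append(MoleculeRecord(mol, rec.source_tag, rec.measurements,
                                  rec.record_name))
    report.add("protonation", len(current), len(out), drops)
    current = out

    # 7. monoprotic filter
    out, drops = [], {}
    for rec in current:
        try:
            keep = monoprotic_filter(rec.mol, predictor, config)
        except Exception as exc:
            drops[_record_key(rec)] = f"predictor failure: {exc}"
            continue
        if keep:
            out.append(rec)
        else:
            drops[_record_key(rec)] = "multiprotic in window"
    report.add("monoprotic", len(current), len(out), drops)
    current = out

    # 8a. prediction-deviation outlier removal (measurement level)
    pairs = [(rec, m) for rec in current for m in rec.measurements]
    out_pairs, drops = [], {}
    for rec, m in pairs:
        predictions = predictor.predict_in_window(rec.mol, config.pka_min,
                                                  config.pka_max)
        if predictions and abs(predictions[0] - m.value) > config.prediction_deviation_cut:
            drops[f"{_record_key(rec)}@{m.value:g}"] = "prediction deviation > cut"
            continue
        out_pairs.append((rec, m))
    report.add("prediction_outliers", len(pairs), len(out_pairs), drops)

    # 8b. merge duplicates by canonical isomeric SMILES
    groups: dict[str, list[float]] = {}
    group_sources: dict[str, set[str]] = {}
    group_mols: dict[str, Chem.Mol] = {}
    for rec, m in out_pairs:
        key = rec.smiles
        groups.setdefault(key, []).append(m.value)
        group_sources.setdefault(key, set()).add(rec.source_tag)
        group_mols.setdefault(key, rec.mol)
    entries = merge_duplicates(groups, config, group_sources, group_mols)
    entries.sort(key=lambda e: e.canonical_smiles)
    report.add("merge_duplicates", len(out_pairs), len(entries), {})
    return entries, report
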