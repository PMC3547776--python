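"""Structure ingestion, normalization, identity keys and mixture detection.

Compound identity in the ontology follows the connection table, not the
input string: two SMILES of ethanol, a kekulized and an aromatic
benzene, or a molecule and its hydrogen-explicit copy must all collapse
onto one key. Standard InChI provides exactly this equivalence and is
used as the structure key throughout (deduplication and exact compound
matching alike); stereochemistry is retained, so enantiomers keep
distinct keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import yaml
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .errors import OntoclassError

# rdkit is chatty about InChI normalization on salts; keep stderr clean.
RDLogger.DisableLog("rdApp.*")

_ALKALI = {3, 11, 19, 37, 55}          # Li Na K Rb Cs
_HALOGEN = {9, 17, 35, 53}             # F Cl Br I

#: counter-ion fragments (canonical SMILES) treated as salt components,
#: not as mixture members
SALT_FRAGMENTS = frozenset(
    ["[Li+]", "[Na+]", "[K+]", "[Rb+]", "[Cs+]",
     "[F-]", "[Cl-]", "[Br-]", "[I-]", "[NH4+]"]
)


@dataclass
class NormalizationConfig:
    """Tunable normalization behaviour.

    salt_handling
        Split covalent alkali-metal/halogen bonds into the ionic form
        (the canonical direction; ``[Na][Cl]`` becomes ``[Na+].[Cl-]``).
    tautomer_collapse
        Canonicalize tautomers. Off by default: compound classes
        represent tautomers as explicit OR-sets of connection tables,
        so collapsing them would make those representations collide.
    keep_failures
        Retain unparseable records (flagged) instead of dropping them.
    """

    salt_handling: bool = True
    tautomer_collapse: bool = False
    keep_failures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "NormalizationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class StructureRecord:
    """One input structure, parsed or flagged."""

    source_id: str
    raw_input: str
    molecule: Optional[Chem.Mol]
    error: Optional[str] = None

    @property
    def fragments(self) -> int:
        if self.molecule is None:
            return 0
        return len(Chem.GetMolFrags(self.molecule))


def _iter_smiles(path: Path) -> Iterator[StructureRecord]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            source_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            mol = Chem.MolFromSmiles(smiles)
            err = None if mol is not None else f"unparseable SMILES: {smiles!r}"
            yield StructureRecord(source_id, line, mol, err)


def _iter_sdf(path: Path) -> Iterator[StructureRecord]:
    # split on the record delimiter ourselves so the raw text of a
    # malformed block survives for reporting
    text = Path(path).read_text()
    blocks = [b for b in text.split("$$$$\n") if b.strip()]
    for i, block in enumerate(blocks):
        mol = Chem.MolFromMolBlock(block, sanitize=True)
        name = block.splitlines()[0].strip() if block.splitlines() else ""
        source_id = name or f"record{i + 1}"
        err = None if mol is not None else "unparseable SDF record"
        yield StructureRecord(source_id, block, mol, err)


def read_structures(path, fmt: Optional[str] = None) -> Iterator[StructureRecord]:
    """Lazily read structures from a ``.smi`` (``SMILES id`` per line) or
    SDF (V2000) file. Invalid records are yielded flagged, never dropped
    silently."""
    path = Path(path)
    if not path.exists():
        raise OntoclassError(f"no such structure file: {path}")
    if fmt is None:
        fmt = "sdf" if path.suffix.lower() in {".sdf", ".sd", ".mol"} else "smiles"
    if fmt not in {"smiles", "sdf"}:
        raise OntoclassError(f"unknown structure format: {fmt!r}")
    return _iter_sdf(path) if fmt == "sdf" else _iter_smiles(path)


def _split_covalent_salts(mol: Chem.Mol) -> Chem.Mol:
    """Break alkali-metal/halogen single bonds into an ion pair."""
    to_split = []
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        nums = {a.GetAtomicNum(), b.GetAtomicNum()}
        if (nums & _ALKALI and nums & _HALOGEN
                and bond.GetBondType() == Chem.BondType.SINGLE
                and a.GetFormalCharge() == 0 and b.GetFormalCharge() == 0):
            to_split.append((a.GetIdx(), b.GetIdx()))
    if not to_split:
        return mol
    rw = Chem.RWMol(mol)
    for ai, bi in to_split:
        rw.RemoveBond(ai, bi)
        for idx in (ai, bi):
            atom = rw.GetAtomWithIdx(idx)
            if atom.GetAtomicNum() in _ALKALI:
                atom.SetFormalCharge(+1)
            else:
                atom.SetFormalCharge(-1)
                atom.SetNoImplicit(True)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def normalize(mol: Chem.Mol, config: Optional[NormalizationConfig] = None) -> Chem.Mol:
    """Sanitize, perceive aromaticity and unify the salt form of a molecule.

    Idempotent: normalizing an already-normalized molecule returns a
    structurally identical one.
    """
    if mol is None:
        raise OntoclassError("cannot normalize an unparsed molecule")
    config = config or NormalizationConfig()
    out = Chem.Mol(mol)
    Chem.SanitizeMol(out)
    if config.salt_handling:
        out = _split_covalent_salts(out)
    if config.tautomer_collapse:
        out = rdMolStandardize.TautomerEnumerator().Canonicalize(out)
    return out


def structure_key(mol: Chem.Mol) -> str:
    """Standard InChI of a normalized molecule; the compound identity key."""
    inchi = Chem.MolToInchi(mol, treatWarningAsError=False)
    if not inchi:
        raise OntoclassError(
            f"InChI generation failed for {Chem.MolToSmiles(mol)!r}"
        )
    return inchi


def is_mixture(mol: Chem.Mol) -> bool:
    """True iff the normalized molecule holds more than one real component.

    Recognized counter-ion fragments (alkali cations, halides, ammonium)
    are salt components: a salt is one compound, not a mixture. If every
    fragment is a counter ion (plain sodium chloride) the structure is a
    salt as well.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return False
    real = [f for f in frags if Chem.MolToSmiles(f) not in SALT_FRAGMENTS]
    return len(real) > 1


def dedupe_by_key(records) -> tuple[list, dict]:
    """Join duplicate structures on structure-key identity.

    Returns (unique_records, key->list-of-source_ids). Records that fail
    normalization or key generation are kept as-is under a None key.
    """
    seen: dict[str, list[str]] = {}
    unique = []
    for rec in records:
        if rec.molecule is None:
            unique.append(rec)
            continue
        try:
            key = structure_key(normalize(rec.molecule))
        except OntoclassError:
            unique.append(rec)
            continue
        if key not in seen:
            seen[key] = []
            unique.append(rec)
        seen[key].append(rec.source_id)
    return unique, seen
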