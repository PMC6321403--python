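"""Ligand preparation: from SMILES to per-compound conformer pharmacophores.

The pipeline is: enumerate unassigned stereocentres, embed up to a
fixed number of conformers per stereoisomer, minimise them with MMFF94
and keep those within an energy window of the best one, then perceive
pharmacophore features on every surviving conformer with a SMARTS
table.  All stereoisomers and conformers of one input compound are kept
together in a :class:`ConformerPharmSet` — downstream model building
and screening treat them as alternative realisations of a single parent
compound.

Everything downstream consumes :class:`ConformerPharmSet` only, so a
synthetic set (see :mod:`pharmsig.synthetic`) is accepted everywhere a
perceived one is.  RDKit is imported lazily inside the functions that
need it.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from .features import FeaturePoint, Pharmacophore

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "ConformerPharmSet",
    "read_compound_table",
    "load_feature_definitions",
    "enumerate_stereoisomers",
    "generate_conformers",
    "perceive_features",
    "prepare_dataset",
    "pharm2d_fingerprints",
]


@dataclass(frozen=True)
class CompoundRecord:
    """One input compound: identifier, SMILES and activity label."""

    compound_id: str
    smiles: str
    activity: str  # "active" or "inactive"

    def __post_init__(self):
        if self.activity not in ("active", "inactive"):
            raise ValueError(f"activity must be active/inactive, got {self.activity!r}")

    @property
    def is_active(self) -> bool:
        return self.activity == "active"


@dataclass
class ConformerPharmSet:
    """All conformer pharmacophores of one parent compound.

    ``members`` holds ``(stereoisomer index, conformer index,
    Pharmacophore)`` triples; stereoisomers of a compound are treated as
    the same parent for counting purposes.
    """

    compound_id: str
    members: list = field(default_factory=list)

    def add(self, stereo_idx: int, conf_idx: int, pharm: Pharmacophore) -> None:
        self.members.append((int(stereo_idx), int(conf_idx), pharm))

    def member_map(self) -> dict:
        return {(s, c): p for s, c, p in self.members}

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def read_compound_table(source) -> list[CompoundRecord]:
    """Read a delimited text table of compounds.

    Accepts a file path or an open text stream.  The table must have a
    header with columns ``smiles``, ``compound_id`` (or ``id``/``name``/
    ``mol_id``) and ``activity`` (``active``/``inactive``,
    case-insensitive), separated by tabs or commas.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    sample = text[:4096]
    delimiter = "\t" if sample.count("\t") >= sample.count(",") else ","
    reader = csv.DictReader(io.StringIO(text), delimiter=delimiter)
    if reader.fieldnames is None:
        return []
    cols = {c.strip().lower(): c for c in reader.fieldnames}
    id_col = next(
        (cols[k] for k in ("compound_id", "id", "mol_id", "name") if k in cols), None
    )
    if "smiles" not in cols or id_col is None or "activity" not in cols:
        raise ValueError(
            "compound table needs columns smiles, compound_id (or id/name) "
            "and activity"
        )
    records = []
    for row in reader:
        records.append(
            CompoundRecord(
                compound_id=row[id_col].strip(),
                smiles=row[cols["smiles"]].strip(),
                activity=row[cols["activity"]].strip().lower(),
            )
        )
    ids = [r.compound_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("compound_id values must be unique")
    return records


def load_feature_definitions(path=None) -> list[tuple[str, str]]:
    """Load a ``label SMARTS`` table (``#`` comments, blank lines ignored).

    With ``path=None`` the packaged default table is used; it is a
    reconstruction of common open pharmacophore definitions and is
    clearly labelled as such in the file itself.
    """
    if path is None:
        text = (
            resources.files("pharmsig").joinpath("data/features.smarts").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    defs = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, smarts = line.split(None, 1)
        defs.append((label, smarts.strip()))
    return defs


def enumerate_stereoisomers(record_or_smiles, max_isomers: int = 32):
    """Enumerate stereoisomers over *unassigned* centres of a molecule.

    Defined stereocentres are preserved; only undefined tetrahedral
    centres and double bonds are enumerated.  Returns a list of RDKit
    molecules with explicit stereochemistry (exactly one for a molecule
    with nothing to enumerate).

    Raises ``ValueError`` for unparsable SMILES; callers that process
    whole datasets catch this and record the compound as skipped.
    """
    from rdkit import Chem
    from rdkit.Chem.EnumerateStereoisomers import (
        EnumerateStereoisomers,
        StereoEnumerationOptions,
    )

    smiles = (
        record_or_smiles.smiles
        if isinstance(record_or_smiles, CompoundRecord)
        else str(record_or_smiles)
    )
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    opts = StereoEnumerationOptions(
        onlyUnassigned=True, maxIsomers=max_isomers, unique=True
    )
    isomers = list(EnumerateStereoisomers(mol, options=opts))
    return isomers if isomers else [mol]


def generate_conformers(
    mol,
    max_conf: int = 100,
    energy_window: float = 50.0,
    seed: int = 42,
):
    """Embed, minimise and energy-filter conformers of one structure.

    Up to ``max_conf`` conformers are embedded (ETKDG, fixed ``seed``),
    minimised with the MMFF94 force field, and only those within
    ``energy_window`` kcal/mol of the lowest-energy conformer are kept.

    Returns ``(mol_with_hs, kept_conf_ids, energies)`` where energies
    are in kcal/mol, aligned with ``kept_conf_ids``.  Raises
    ``RuntimeError`` when embedding fails entirely.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    cids = list(AllChem.EmbedMultipleConfs(molh, numConfs=int(max_conf), params=params))
    if not cids:
        raise RuntimeError("conformer embedding failed")
    results = AllChem.MMFFOptimizeMoleculeConfs(molh, maxIters=500)
    energies = {}
    for cid, (converged, energy) in zip(cids, results):
        if converged in (0, 1) and energy == energy:  # not NaN
            energies[cid] = float(energy)
    if not energies:
        raise RuntimeError("MMFF minimisation failed for all conformers")
    emin = min(energies.values())
    kept = [cid for cid in cids if cid in energies and energies[cid] - emin <= energy_window]
    return molh, kept, [energies[cid] for cid in kept]


def perceive_features(
    mol,
    conf_id: int,
    feature_defs: Sequence[tuple[str, str]],
    bin_step: float = 1.0,
) -> Pharmacophore:
    """Map SMARTS feature definitions onto one conformer.

    Every match of every pattern produces one feature point at the
    centroid of the matched atoms (hydrogens included if matched).  A
    given atom set yields at most one point per label, but may carry
    several labels simultaneously — e.g. an aromatic ring is both
    aromatic and hydrophobic, giving two coincident points.
    """
    from rdkit import Chem

    conf = mol.GetConformer(conf_id)
    seen = set()
    feats = []
    for label, smarts in feature_defs:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid SMARTS for feature {label!r}: {smarts!r}")
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            key = (label, frozenset(match))
            if key in seen:
                continue
            seen.add(key)
            xs = [conf.GetAtomPosition(a) for a in match]
            n = len(xs)
            cx = sum(p.x for p in xs) / n
            cy = sum(p.y for p in xs) / n
            cz = sum(p.z for p in xs) / n
            feats.append(FeaturePoint(label, cx, cy, cz))
    return Pharmacophore(feats, bin_step=bin_step)


def prepare_dataset(
    records: Iterable[CompoundRecord],
    feature_defs=None,
    bin_step: float = 1.0,
    max_conf: int = 100,
    energy_window: float = 50.0,
    seed: int = 42,
    max_isomers: int = 32,
):
    """Run the full preparation pipeline over a compound table.

    Returns ``(conformer_sets, skipped)`` where ``conformer_sets`` maps
    compound_id to :class:`ConformerPharmSet` and ``skipped`` is a
    manifest of ``(compound_id, reason)`` for records that failed
    parsing or embedding (they are logged, never fatal).
    """
    if feature_defs is None:
        feature_defs = load_feature_definitions()
    sets: dict[str, ConformerPharmSet] = {}
    skipped: list[tuple[str, str]] = []
    for rec in records:
        try:
            isomers = enumerate_stereoisomers(rec, max_isomers=max_isomers)
        except ValueError as exc:
            logger.warning("skipping %s: %s", rec.compound_id, exc)
            skipped.append((rec.compound_id, str(exc)))
            continue
        cps = ConformerPharmSet(rec.compound_id)
        for si, isomer in enumerate(isomers):
            try:
                molh, cids, _ = generate_conformers(
                    isomer, max_conf=max_conf, energy_window=energy_window, seed=seed
                )
            except RuntimeError as exc:
                logger.warning(
                    "embedding failed for %s stereoisomer %d: %s",
                    rec.compound_id, si, exc,
                )
                continue
            for ci, cid in enumerate(cids):
                pharm = perceive_features(molh, cid, feature_defs, bin_step=bin_step)
                cps.add(si, ci, pharm)
        if len(cps) == 0:
            skipped.append((rec.compound_id, "no conformers generated"))
            continue
        sets[rec.compound_id] = cps
    return sets, skipped


def pharm2d_fingerprints(records: Iterable[CompoundRecord]) -> dict:
    """Topological (2D) pharmacophore-pair fingerprints for clustering.

    Uses RDKit's Gobbi 2D pharmacophore fingerprints; the exact flavour
    is a configuration choice, not a contract — any fingerprint with a
    Tanimoto similarity works for training-set design.  Unparsable
    SMILES are skipped with a warning.
    """
    from rdkit import Chem
    from rdkit.Chem.Pharm2D import Generate, Gobbi_Pharm2D

    fps = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("skipping %s: unparsable SMILES", rec.compound_id)
            continue
        fps[rec.compound_id] = Generate.Gen2DFingerprint(mol, Gobbi_Pharm2D.factory)
    return fps
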