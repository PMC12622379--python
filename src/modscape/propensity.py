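"""Amino-acid propensity-index bundles for sequence featurization.

A *propensity index* maps each of the 20 canonical residues to a real number
(hydropathy, flexibility, surface propensity, ...). A protein's feature vector
is the composition-weighted mean of each index over its sequence, so proteins
of similar residue composition land near each other regardless of length.

The default bundle is assembled deterministically at import time from:

* every unique published per-residue scale shipped with Biopython
  (``Bio.SeqUtils.ProtParamData`` — Kyte–Doolittle and 27 further hydropathy
  scales, Hopp–Woods hydrophilicity, Emini surface accessibility, Janin
  interior-to-surface, Vihinen flexibility, ... de-duplicated to 32 distinct
  value tables);
* exactly-stated physicochemical tables (average residue mass, net side-chain
  charge at pH 7, and residue-class indicators: aromatic, aliphatic, polar,
  charged, tiny, small, hydroxyl-bearing, sulfur-bearing, amide);
* seeded **synthetic** scales, named ``synthetic_NN`` and drawn once from a
  fixed-seed standard normal, used only to pad the bundle to the requested
  width. They add discriminative coordinates but correspond to no measured
  property; swap in a curated list via :func:`load_index_set` when one is
  available.

The bundle width defaults to 60 features. The index names and a content hash
are exposed so runs can record exactly which bundle produced a network.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils import ProtParamData

from .errors import ValidationError

CANONICAL_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")
_RES_SET = frozenset(CANONICAL_RESIDUES)

#: net side-chain charge at pH 7 (His given its ~10% protonated fraction)
_CHARGE = {r: 0.0 for r in CANONICAL_RESIDUES}
_CHARGE.update({"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.1})

_CLASSES = {
    "indicator_aromatic": "FWYH",
    "indicator_aliphatic": "AVLI",
    "indicator_polar": "STNQCYH",
    "indicator_positive": "KRH",
    "indicator_negative": "DE",
    "indicator_tiny": "AGSC",
    "indicator_small": "AGSCTDNPV",
    "indicator_hydroxyl": "STY",
    "indicator_sulfur": "CM",
    "indicator_amide": "NQ",
}


@dataclass(frozen=True)
class IndexSet:
    """An ordered bundle of named propensity indices."""

    names: tuple[str, ...]
    tables: tuple[dict, ...]

    def __len__(self) -> int:
        return len(self.tables)

    @property
    def content_hash(self) -> str:
        """Stable hash of names and values, for run metadata."""
        h = hashlib.sha256()
        for name, table in zip(self.names, self.tables):
            h.update(name.encode())
            for r in CANONICAL_RESIDUES:
                h.update(np.float64(table[r]).tobytes())
        return h.hexdigest()[:16]


def _published_tables() -> dict[str, dict]:
    """Unique published scales from Biopython, keyed by a stable name."""
    raw: dict[str, dict] = {}
    for name in dir(ProtParamData):
        obj = getattr(ProtParamData, name)
        if (
            isinstance(obj, dict)
            and set(obj.keys()) == _RES_SET
            and all(isinstance(v, (int, float)) for v in obj.values())
        ):
            raw[f"protparam_{name}"] = obj
    for name, table in ProtParamData.gravy_scales.items():
        if set(table.keys()) == _RES_SET:
            raw[f"gravy_{name}"] = table
    unique: dict[str, dict] = {}
    seen: set[tuple] = set()
    for name in sorted(raw):
        key = tuple(round(float(raw[name][r]), 9) for r in CANONICAL_RESIDUES)
        if key not in seen:
            seen.add(key)
            unique[name] = {r: float(raw[name][r]) for r in CANONICAL_RESIDUES}
    return unique


def default_index_set(n_indices: int = 60, pad_seed: int = 20240901) -> IndexSet:
    """Assemble the default bundle, padded (or truncated) to ``n_indices``.

    Deterministic: the same arguments always return an identical bundle.
    """
    names: list[str] = []
    tables: list[dict] = []
    for name, table in _published_tables().items():
        names.append(name)
        tables.append(table)
    names.append("residue_mass")
    tables.append({r: float(protein_weights[r]) for r in CANONICAL_RESIDUES})
    names.append("charge_ph7")
    tables.append(dict(_CHARGE))
    for name, members in _CLASSES.items():
        names.append(name)
        tables.append({r: float(r in members) for r in CANONICAL_RESIDUES})
    if n_indices < len(tables):
        names, tables = names[:n_indices], tables[:n_indices]
    else:
        rng = np.random.default_rng(pad_seed)
        for i in range(n_indices - len(tables)):
            vals = rng.standard_normal(len(CANONICAL_RESIDUES))
            names.append(f"synthetic_{i:02d}")
            tables.append(dict(zip(CANONICAL_RESIDUES, map(float, vals))))
    return IndexSet(names=tuple(names), tables=tuple(tables))


def load_index_set(path: str | Path) -> IndexSet:
    """Load a bundle from TSV: ``name`` column then one column per residue."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = _RES_SET - set(df.columns)
    if missing:
        raise ValidationError(f"index table missing residue column(s) {sorted(missing)}")
    names = tuple(str(n) for n in df.index)
    tables = tuple(
        {r: float(df.loc[n, r]) for r in CANONICAL_RESIDUES} for n in df.index
    )
    return IndexSet(names=names, tables=tables)


def write_index_set(index_set: IndexSet, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        [[t[r] for r in CANONICAL_RESIDUES] for t in index_set.tables],
        index=list(index_set.names),
        columns=list(CANONICAL_RESIDUES),
    ).to_csv(path, sep="\t", index_label="name")
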