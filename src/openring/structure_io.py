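"""Coordinate I/O and coarse-graining.

Atomic models are held in :class:`AtomSet`, a plain struct-of-arrays container
(coordinates in Å plus per-atom annotation).  Reading and writing of PDB and
mmCIF files is delegated to :mod:`gemmi`; this module only adapts between
gemmi's hierarchy and the flat arrays the rest of the pipeline consumes.

Conventions
-----------
* Coordinates are always Å.
* Alternate locations: only the highest-occupancy conformer of each atom is
  kept.
* Waters and (by default) other heteroatoms are excluded; the analyses in this
  package are protein-only.
* Selenomethionine (MSE) is renamed to MET so residue-level selections and
  sequence operations treat it as methionine; the Se element symbol is kept
  for scattering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: chain identifiers usable in fixed-column PDB files
_PDB_CHAIN_IDS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)


@dataclass
class AtomSet:
    """Coordinates plus per-atom annotation for a structure or bead model.

    All per-atom fields are parallel arrays of equal length.  ``is_bead``
    marks coarse-grained pseudo-atom sets produced by :func:`coarse_grain`
    (their ``elements`` then carry a residue-level scattering label rather
    than a chemical element).
    """

    coords: np.ndarray  # (n, 3) float64, Å
    elements: np.ndarray  # (n,) str, element symbol or bead label
    atom_names: np.ndarray  # (n,) str
    chain_ids: np.ndarray  # (n,) str
    residue_numbers: np.ndarray  # (n,) int
    insertion_codes: np.ndarray  # (n,) str ('' if none)
    residue_names: np.ndarray  # (n,) str, 3-letter codes
    is_bead: bool = False
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        for name in ("elements", "atom_names", "chain_ids", "residue_numbers",
                     "insertion_codes", "residue_names"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(
                    f"AtomSet field {name!r} has length {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("AtomSet coordinates must be finite")
        if any(c == "" for c in self.chain_ids):
            raise ValueError("chain ids must be non-empty strings")

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c))
        return list(seen)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def radius_of_gyration(self) -> float:
        d = self.coords - self.centroid()
        return float(np.sqrt((d * d).sum(axis=1).mean()))

    def take(self, index: np.ndarray) -> "AtomSet":
        """Subset by boolean mask or integer index array, preserving order."""
        return AtomSet(
            coords=self.coords[index],
            elements=self.elements[index],
            atom_names=self.atom_names[index],
            chain_ids=self.chain_ids[index],
            residue_numbers=self.residue_numbers[index],
            insertion_codes=self.insertion_codes[index],
            residue_names=self.residue_names[index],
            is_bead=self.is_bead,
            source_label=self.source_label,
        )

    def with_coords(self, coords: np.ndarray) -> "AtomSet":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def with_chain_ids(self, chain_ids: np.ndarray) -> "AtomSet":
        return replace(self, chain_ids=np.asarray(chain_ids))

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered distinct (chain, residue number, insertion code) triples."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_ids, self.residue_numbers,
                           self.insertion_codes):
            seen.setdefault((str(c), int(r), str(i)))
        return list(seen)


def concat_atom_sets(sets: list[AtomSet]) -> AtomSet:
    if not sets:
        raise ValueError("cannot concatenate zero AtomSets")
    return AtomSet(
        coords=np.concatenate([s.coords for s in sets]),
        elements=np.concatenate([s.elements for s in sets]),
        atom_names=np.concatenate([s.atom_names for s in sets]),
        chain_ids=np.concatenate([s.chain_ids for s in sets]),
        residue_numbers=np.concatenate([s.residue_numbers for s in sets]),
        insertion_codes=np.concatenate([s.insertion_codes for s in sets]),
        residue_names=np.concatenate([s.residue_names for s in sets]),
        is_bead=all(s.is_bead for s in sets),
        source_label=sets[0].source_label,
    )


# ---------------------------------------------------------------------------
# reading


def _best_altloc_mask(residue: gemmi.Residue) -> list[bool]:
    """Keep one conformer per atom name: the highest-occupancy altloc."""
    best: dict[str, tuple[float, int]] = {}
    for i, atom in enumerate(residue):
        occ = atom.occ if atom.occ is not None else 1.0
        key = atom.name
        if key not in best or occ > best[key][0]:
            best[key] = (occ, i)
    keep = {i for _, i in best.values()}
    return [i in keep for i in range(len(residue))]


def read_structure(path, model_index: int = 0,
                   include_hetero: bool = False) -> AtomSet:
    """Read a PDB or mmCIF file (gzip-transparent) into an :class:`AtomSet`.

    Parameters
    ----------
    path
        Coordinate file; dialect detected from extension/content by gemmi.
    model_index
        0-based model to extract (NMR-style multi-model files).
    include_hetero
        If False (default) non-polymer heteroatoms are skipped.  Waters are
        always skipped.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    st.setup_entities()
    if not (0 <= model_index < len(st)):
        raise IndexError(
            f"model_index {model_index} out of range: file has {len(st)} model(s)")
    model = st[model_index]

    coords, elements, names = [], [], []
    chains, resnums, icodes, resnames = [], [], [], []
    for chain in model:
        for residue in chain:
            rname = residue.name
            if rname in _WATER_NAMES:
                continue
            is_polymer = residue.entity_type in (
                gemmi.EntityType.Polymer, gemmi.EntityType.Unknown)
            info = gemmi.find_tabulated_residue(rname)
            is_aa = info is not None and info.is_amino_acid()
            if not include_hetero and not (is_polymer or is_aa):
                continue
            out_name = "MET" if rname == "MSE" else rname
            mask = _best_altloc_mask(residue)
            for atom, keep in zip(residue, mask):
                if not keep:
                    continue
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name.upper())
                names.append(atom.name)
                chains.append(chain.name)
                resnums.append(residue.seqid.num)
                icodes.append(residue.seqid.icode.strip())
                resnames.append(out_name)
    if not coords:
        raise ValueError(f"no atoms read from {path}")
    return AtomSet(
        coords=np.array(coords, dtype=float),
        elements=np.array(elements, dtype=object),
        atom_names=np.array(names, dtype=object),
        chain_ids=np.array(chains, dtype=object),
        residue_numbers=np.array(resnums, dtype=int),
        insertion_codes=np.array(icodes, dtype=object),
        residue_names=np.array(resnames, dtype=object),
        source_label=str(path),
    )


# ---------------------------------------------------------------------------
# selection


def select_atoms(atoms: AtomSet, chains=None, atom_names=None,
                 heavy_only: bool = False) -> AtomSet:
    """Subset an AtomSet, preserving atom order.

    ``chains`` and ``atom_names`` are optional allow-lists; ``heavy_only``
    drops hydrogens.  An empty selection is legal but logged as a warning.
    """
    mask = np.ones(len(atoms), dtype=bool)
    if chains is not None:
        chain_set = {str(c) for c in chains}
        mask &= np.array([str(c) in chain_set for c in atoms.chain_ids])
    if atom_names is not None:
        name_set = set(atom_names)
        mask &= np.array([n in name_set for n in atoms.atom_names])
    if heavy_only:
        mask &= np.array([e not in ("H", "D") for e in atoms.elements])
    if not mask.any():
        logger.warning("select_atoms produced an empty selection "
                       "(chains=%r, atom_names=%r)", chains, atom_names)
    return atoms.take(mask)


# ---------------------------------------------------------------------------
# writing


def _chain_layout(atoms: AtomSet, relabel: bool):
    """Return (per-atom chain labels, original->output chain map)."""
    orig = atoms.chains
    if not relabel:
        return atoms.chain_ids, {c: c for c in orig}
    if len(orig) > len(_PDB_CHAIN_IDS):
        raise ValueError(
            f"{len(orig)} chains exceed the {len(_PDB_CHAIN_IDS)} single-character "
            "ids available in the PDB dialect; write mmCIF (.cif) instead")
    mapping = {c: _PDB_CHAIN_IDS[i] for i, c in enumerate(orig)}
    labels = np.array([mapping[str(c)] for c in atoms.chain_ids], dtype=object)
    return labels, mapping


def write_structure(atoms_or_assembly, path) -> dict[str, str]:
    """Write an AtomSet or Assembly as PDB (.pdb) or mmCIF (.cif/.mmcif).

    Assembly copies are expanded to distinct chains (copy index appended to
    the seed's chain ids before any PDB re-lettering).  Returns the
    original-chain -> written-chain map.
    """
    from .assembly import Assembly  # local import: avoid cycle

    if isinstance(atoms_or_assembly, Assembly):
        atoms = atoms_or_assembly.to_atomset()
    else:
        atoms = atoms_or_assembly

    path = str(path)
    as_pdb = not path.lower().endswith((".cif", ".mmcif", ".cif.gz"))
    needs_relabel = as_pdb and any(len(str(c)) != 1 for c in atoms.chains)
    if as_pdb and len(atoms.chains) > len(_PDB_CHAIN_IDS):
        raise ValueError(
            f"{len(atoms.chains)} chains do not fit the PDB dialect; "
            "use an .cif extension for mmCIF output")
    labels, mapping = _chain_layout(atoms, relabel=needs_relabel)

    st = gemmi.Structure()
    st.name = atoms.source_label or "openring"
    model = gemmi.Model("1")
    current_chain = None
    chain_obj = None
    res_obj = None
    current_res = None
    for i in range(len(atoms)):
        cid = str(labels[i])
        if cid != current_chain:
            chain_obj = gemmi.Chain(cid)
            model.add_chain(chain_obj)
            chain_obj = model[-1]
            current_chain = cid
            current_res = None
        rkey = (int(atoms.residue_numbers[i]), str(atoms.insertion_codes[i]),
                str(atoms.residue_names[i]))
        if rkey != current_res:
            res = gemmi.Residue()
            res.name = rkey[2]
            res.seqid = gemmi.SeqId(rkey[0], rkey[1] or " ")
            chain_obj.add_residue(res)
            res_obj = chain_obj[-1]
            current_res = rkey
        atom = gemmi.Atom()
        atom.name = str(atoms.atom_names[i])
        el = str(atoms.elements[i])
        ge = gemmi.Element(el)
        # bead labels (e.g. RES) are not chemical elements: write them as C
        atom.element = (ge if ge.atomic_number > 0
                        and ge.name.upper() == el.upper()
                        else gemmi.Element("C"))
        x, y, z = atoms.coords[i]
        atom.pos = gemmi.Position(float(x), float(y), float(z))
        atom.occ = 1.0
        atom.b_iso = 0.0
        res_obj.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    if as_pdb:
        st.write_pdb(path)
    else:
        st.make_mmcif_document().write_file(path)
    return mapping


# ---------------------------------------------------------------------------
# coarse graining


def coarse_grain(atoms: AtomSet, bead_label: str = "RES") -> AtomSet:
    """One bead per residue, placed exactly on the CA atom.

    Beads carry ``bead_label`` in their element slot; the scattering table
    maps it to an effective per-residue scattering length.  Residues without
    a CA atom are skipped with a warning reporting the count.
    """
    ca = select_atoms(atoms, atom_names=["CA"])
    n_res = len(atoms.residues())
    n_skipped = n_res - len(ca.residues())
    if len(ca) == 0:
        raise ValueError("coarse_grain requires at least one residue with a CA atom")
    if n_skipped:
        warnings.warn(f"coarse_grain: {n_skipped} residue(s) lack a CA atom "
                      "and were skipped")
    beads = replace(
        ca,
        elements=np.array([bead_label] * len(ca), dtype=object),
        atom_names=np.array(["CA"] * len(ca), dtype=object),
        is_bead=True,
    )
    return beads
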