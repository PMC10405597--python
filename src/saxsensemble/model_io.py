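"""Atomic model I/O and per-residue confidence handling.

Models are read from PDB/mmCIF files that follow the AlphaFold convention of
storing the per-residue confidence (pLDDT, 0-100) in the B-factor column.
Only heavy protein atoms are kept; hydrogens, waters and heteroatoms are
dropped.  Scattering factors follow a united-atom convention: the electrons
of implicit hydrogens are folded into their parent heavy atom, and each
atomic group carries a radius used both for the solvent-displacement term

    b0 = 10 * (radius / r_wat)**3,   r_wat = 1.93 A

and for steric-clash detection during Monte Carlo sampling.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

#: radius of a bulk water molecule, Angstrom
R_WATER = 1.93
#: electrons in a water molecule
WATER_ELECTRONS = 10.0

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class AtomSite:
    """One (united-)atomic group of a protein model."""

    serial: int
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    xyz: np.ndarray
    confidence: float
    name: str = ""
    b: float = 0.0          # electrons of the group (implicit H folded in)
    b0: float = 0.0         # solvent-displaced electrons
    radius: float = 0.0     # group radius, Angstrom


@dataclass
class ProteinModel:
    """Ordered collection of atomic groups plus derived per-atom arrays.

    Internally array-backed for speed; :meth:`atom` returns an
    :class:`AtomSite` view of a single atom.
    """

    coords: np.ndarray                  # (n, 3) float
    elements: np.ndarray                # (n,) str
    atom_names: np.ndarray              # (n,) str
    residue_index: np.ndarray           # (n,) int, 1-based, non-decreasing
    residue_names: np.ndarray           # (n,) str
    chain_id: str = "A"
    confidence: np.ndarray | None = None    # per atom, pLDDT
    b: np.ndarray | None = None
    b0: np.ndarray | None = None
    radius: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.confidence is None:
            self.confidence = np.zeros(len(self.coords))

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def n_residues(self) -> int:
        return len(np.unique(self.residue_index))

    @property
    def sequence(self) -> str:
        """1-letter sequence; 'X' for residues without a standard 3-letter code."""
        seq = []
        seen = set()
        for idx, name in zip(self.residue_index, self.residue_names):
            if idx not in seen:
                seen.add(idx)
                seq.append(THREE_TO_ONE.get(str(name), "X"))
        return "".join(seq)

    def atom(self, i: int) -> AtomSite:
        return AtomSite(
            serial=i + 1,
            element=str(self.elements[i]),
            residue_index=int(self.residue_index[i]),
            residue_name=str(self.residue_names[i]),
            chain_id=self.chain_id,
            xyz=self.coords[i],
            confidence=float(self.confidence[i]),
            name=str(self.atom_names[i]),
            b=float(self.b[i]) if self.b is not None else 0.0,
            b0=float(self.b0[i]) if self.b0 is not None else 0.0,
            radius=float(self.radius[i]) if self.radius is not None else 0.0,
        )

    @property
    def atoms(self) -> list[AtomSite]:
        return [self.atom(i) for i in range(self.n_atoms)]

    @property
    def contrast(self) -> np.ndarray:
        """Effective per-group contrast w = b - b0 (electrons)."""
        if self.b is None or self.b0 is None:
            raise ValueError("scattering factors not assigned")
        return self.b - self.b0

    def residue_confidence(self) -> tuple[np.ndarray, np.ndarray]:
        """(residue indices, per-residue confidence) taking one value per residue."""
        idx, first = np.unique(self.residue_index, return_index=True)
        # prefer the CA atom of each residue when present
        conf = self.confidence[first].astype(float).copy()
        ca = self.atom_names == "CA"
        for k, ri in enumerate(idx):
            sel = ca & (self.residue_index == ri)
            if sel.any():
                conf[k] = float(self.confidence[np.flatnonzero(sel)[0]])
        return idx, conf

    def copy(self) -> "ProteinModel":
        return replace(
            self,
            coords=self.coords.copy(),
            elements=self.elements.copy(),
            atom_names=self.atom_names.copy(),
            residue_index=self.residue_index.copy(),
            residue_names=self.residue_names.copy(),
            confidence=None if self.confidence is None else self.confidence.copy(),
            b=None if self.b is None else self.b.copy(),
            b0=None if self.b0 is None else self.b0.copy(),
            radius=None if self.radius is None else self.radius.copy(),
        )


@dataclass
class SegmentSpec:
    """Inclusive 1-based residue ranges marked as flexible."""

    ranges: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        for first, last in self.ranges:
            if first > last:
                raise ValueError(f"segment ({first}, {last}): first > last")
        srt = sorted(self.ranges)
        for (a0, a1), (b0_, _) in zip(srt, srt[1:]):
            if b0_ <= a1:
                raise ValueError("segments overlap")
        self.ranges = srt

    def __len__(self):
        return len(self.ranges)

    def contains(self, residue_index: int) -> bool:
        return any(a <= residue_index <= b for a, b in self.ranges)

    def residues(self) -> list[int]:
        out: list[int] = []
        for a, b in self.ranges:
            out.extend(range(a, b + 1))
        return out


@dataclass
class ConfidenceSummary:
    mean: float
    sd: float
    n_residues: int

    def __str__(self):
        return f"{self.mean:.0f} ± {self.sd:.0f}% over {self.n_residues} residues"


# ---------------------------------------------------------------------------
# factor table


def load_factor_table(path=None) -> dict[tuple[str, str], tuple[float, float]]:
    """Load the united-atom group table: (residue, atom) -> (electrons, radius).

    Residue '*' entries act as wildcards for backbone atoms.
    """
    if path is None:
        ref = importlib.resources.files("saxsensemble.data") / "scattering_groups.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        res, atom, _elem, ne, rad = line.split("\t")
        table[(res, atom)] = (float(ne), float(rad))
    return table


def assign_scattering_factors(model: ProteinModel, factor_table=None) -> ProteinModel:
    """Assign united-atom electrons, radii and b0 = 10*(r/r_wat)^3 to every atom.

    Returns a new model; the input is not modified.  Raises ``KeyError``
    listing all (residue, atom) combinations absent from the table.
    """
    if factor_table is None:
        factor_table = load_factor_table()
    out = model.copy()
    n = out.n_atoms
    b = np.empty(n)
    radius = np.empty(n)
    missing = []
    for i in range(n):
        key = (str(out.residue_names[i]), str(out.atom_names[i]))
        hit = factor_table.get(key) or factor_table.get(("*", key[1]))
        if hit is None:
            missing.append(key)
            continue
        b[i], radius[i] = hit
    if missing:
        uniq = sorted(set(missing))
        raise KeyError(f"no scattering group for atoms: {uniq}")
    out.b = b
    out.radius = radius
    out.b0 = solvent_displaced_electrons(radius)
    return out


def solvent_displaced_electrons(radius) -> np.ndarray:
    """b0 = 10*(r/r_wat)^3: electrons of water displaced by a group of radius r."""
    return WATER_ELECTRONS * (np.asarray(radius, dtype=float) / R_WATER) ** 3


# ---------------------------------------------------------------------------
# reading


def read_model(path, format_hint: str | None = None, chain: str | None = None) -> ProteinModel:
    """Read a predicted structure (PDB or mmCIF) with pLDDT in the B column.

    Keeps heavy protein atoms of the first model; refuses multi-chain files
    unless ``chain`` names one.  Confidence is taken from each residue's CA
    atom and inherited by all atoms of the residue.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: empty structure")
    gmodel = st[0]
    chains = [ch.name for ch in gmodel]
    if chain is None:
        polymer_chains = [ch for ch in gmodel if any(
            gemmi.find_tabulated_residue(r.name) is not None
            and gemmi.find_tabulated_residue(r.name).is_amino_acid()
            or any(a.name == "CA" for a in r) for r in ch)]
        if len(polymer_chains) > 1:
            raise ValueError(
                f"{path}: multiple chains {chains}; select one with chain=")
        if not polymer_chains:
            raise ValueError(f"{path}: empty model (no protein atoms)")
        gchain = polymer_chains[0]
    else:
        try:
            gchain = gmodel[chain]
        except Exception as exc:  # gemmi raises on missing chain
            raise ValueError(f"{path}: chain {chain!r} not found in {chains}") from exc

    coords, elements, names, ridx, rnames, conf = [], [], [], [], [], []
    for res in gchain:
        if res.het_flag == "H" or res.name == "HOH":
            continue
        ca_b = None
        for atom in res:
            if atom.name == "CA" and atom.element.name != "Ca":
                ca_b = atom.b_iso
                break
        for atom in res:
            el = atom.element.name
            if el == "H" or el == "D":
                continue
            if atom.altloc not in ("", "A", "\x00"):
                continue  # take first altloc only
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            elements.append(el)
            names.append(atom.name)
            ridx.append(res.seqid.num)
            rnames.append(res.name)
            conf.append(ca_b if ca_b is not None else atom.b_iso)
    if not coords:
        raise ValueError(f"{path}: empty model (no protein atoms)")
    return ProteinModel(
        coords=np.array(coords),
        elements=np.array(elements, dtype=object),
        atom_names=np.array(names, dtype=object),
        residue_index=np.array(ridx, dtype=int),
        residue_names=np.array(rnames, dtype=object),
        chain_id=gchain.name,
        confidence=np.array(conf, dtype=float),
        label=str(path),
    )


# ---------------------------------------------------------------------------
# confidence summaries / flexible-segment suggestion


def segment_confidence(model: ProteinModel, segment: tuple[int, int] | SegmentSpec) -> ConfidenceSummary:
    """Mean and population SD of per-residue pLDDT over a residue segment."""
    if isinstance(segment, SegmentSpec):
        wanted = set(segment.residues())
    else:
        first, last = segment
        wanted = set(range(first, last + 1))
    idx, conf = model.residue_confidence()
    mask = np.isin(idx, list(wanted))
    if not mask.any():
        raise ValueError("empty segment: no residues in range")
    vals = conf[mask]
    return ConfidenceSummary(mean=float(vals.mean()),
                             sd=float(vals.std()),  # population SD
                             n_residues=int(mask.sum()))


def suggest_flexible_segments(model: ProteinModel, confidence_threshold: float = 60.0,
                              min_length: int = 5) -> SegmentSpec:
    """Maximal runs of >= min_length consecutive residues below the pLDDT threshold.

    Advisory only: an explicit user segment specification always overrides.
    """
    if confidence_threshold <= 0 or min_length <= 0:
        raise ValueError("thresholds must be positive")
    idx, conf = model.residue_confidence()
    low = conf < confidence_threshold
    ranges = []
    start = None
    for k in range(len(idx)):
        if low[k]:
            if start is None or idx[k] != idx[k - 1] + 1:
                if start is not None and k - start >= min_length:
                    ranges.append((int(idx[start]), int(idx[k - 1])))
                start = k
            run_ends = k == len(idx) - 1 or not low[k + 1] or idx[k + 1] != idx[k] + 1
            if run_ends:
                if k - start + 1 >= min_length:
                    ranges.append((int(idx[start]), int(idx[k])))
                start = None
    return SegmentSpec(ranges=ranges)


# ---------------------------------------------------------------------------
# multi-model PDB pool I/O


def _format_atom_line(serial, name, resname, chain, resseq, xyz, b, element):
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"ATOM  {serial % 100000:5d} {name_field}{'':1s}{resname:>3s} {chain:1s}"
            f"{resseq % 10000:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{b:6.2f}          {element:>2s}")


def write_pool(models: list[ProteinModel], path) -> None:
    """Write models as a MODEL/ENDMDL-delimited multi-model PDB file."""
    if not models:
        raise ValueError("empty model list")
    n0 = models[0].n_atoms
    for m in models:
        if m.n_atoms != n0:
            raise ValueError("inconsistent atom counts across models")
    with open(path, "w") as fh:
        for k, m in enumerate(models, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            for i in range(m.n_atoms):
                fh.write(_format_atom_line(
                    i + 1, str(m.atom_names[i]), str(m.residue_names[i]),
                    m.chain_id, int(m.residue_index[i]), m.coords[i],
                    float(m.confidence[i]), str(m.elements[i])) + "\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pool(path) -> list[ProteinModel]:
    """Read a MODEL/ENDMDL multi-model PDB written by :func:`write_pool`."""
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    models = []
    for gmodel in st:
        gchain = gmodel[0]
        coords, elements, names, ridx, rnames, conf = [], [], [], [], [], []
        for res in gchain:
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name)
                names.append(atom.name)
                ridx.append(res.seqid.num)
                rnames.append(res.name)
                conf.append(atom.b_iso)
        models.append(ProteinModel(
            coords=np.array(coords),
            elements=np.array(elements, dtype=object),
            atom_names=np.array(names, dtype=object),
            residue_index=np.array(ridx, dtype=int),
            residue_names=np.array(rnames, dtype=object),
            chain_id=gchain.name,
            confidence=np.array(conf, dtype=float),
            label=f"{path}#{len(models) + 1}",
        ))
    n0 = models[0].n_atoms
    if any(m.n_atoms != n0 for m in models):
        raise ValueError(f"{path}: inconsistent atom counts across models")
    return models
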