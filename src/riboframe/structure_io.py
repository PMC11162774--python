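"""Structure reading and the mRNA reading-frame register.

This module turns a deposited ribosome coordinate file (mmCIF or legacy
PDB) into a light-weight atom table, identifies the functional RNA chains
(16S rRNA, 23S rRNA, mRNA, tRNAs) and establishes the mRNA position
register used throughout the survey: position +1 is the first base of the
P-site codon, negative positions run 5' of it (E-site side); there is no
position 0.

File parsing is delegated to gemmi; everything downstream works on the
:class:`RibosomeStructure` container so synthetic fixtures and deposited
structures flow through identical code.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import (
    ChainUnresolvedError,
    ModelNotFoundError,
    RegisterUnresolvedError,
    StructureFormatError,
)

# Residue names accepted as RNA (canonical + common modifications + abasic).
_RNA_NAMES = {
    "A", "C", "G", "U", "I", "N",
    "PSU", "5MU", "1MA", "OMC", "OMG", "2MG", "7MG", "M2G", "4SU",
    "5MC", "H2U", "UR3", "A2M", "MIA", "4OC", "MA6", "G7M", "M7A",
}

# Watson-Crick edge heavy atoms, used for codon:anticodon pairing checks.
_WC_EDGE = {
    "A": ("N1", "C2", "N6"),
    "G": ("N1", "C2", "O6", "N2"),
    "C": ("N3", "O2", "N4"),
    "U": ("N3", "O2", "O4"),
}


class Atom(NamedTuple):
    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    xyz: tuple  # (x, y, z) in Angstrom


ResidueKey = tuple  # (residue_number, insertion_code)


@dataclass
class RibosomeStructure:
    """Parsed atoms of one model of a ribosome complex.

    Coordinates are in Angstrom. Insertion codes are kept as part of the
    residue identity and ordered after their base number.
    """

    pdb_id: str
    atoms: list
    resolution: float | None = None
    method: str = "other"  # {"xray", "cryoem", "other"}
    model_number: int = 1
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def _build_index(self) -> None:
        idx: dict = {}
        for a in self.atoms:
            ch = idx.setdefault(a.chain_id, {})
            res = ch.setdefault((a.residue_number, a.insertion_code), {})
            res.setdefault("name", a.residue_name)
            res.setdefault("atoms", {})[a.atom_name] = np.asarray(a.xyz, float)
        self._index = idx

    @property
    def index(self) -> dict:
        if not self._index:
            self._build_index()
        return self._index

    def chain_ids(self) -> list:
        return list(self.index.keys())

    def chain_residues(self, chain_id: str) -> list:
        """Residue keys of a chain, ordered by (number, insertion code)."""
        return sorted(self.index[chain_id].keys(), key=lambda k: (k[0], k[1]))

    def residue_name(self, chain_id: str, number: int, icode: str = "") -> str | None:
        res = self.index.get(chain_id, {}).get((number, icode))
        return None if res is None else res["name"]

    def residue_atoms(self, chain_id: str, number: int, icode: str = "") -> dict:
        """Mapping atom name -> xyz array, empty if the residue is absent."""
        res = self.index.get(chain_id, {}).get((number, icode))
        return {} if res is None else dict(res["atoms"])

    def validate(self) -> None:
        if not self.atoms:
            raise ValueError("structure has no atoms")
        coords = np.array([a.xyz for a in self.atoms], float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates present")


def is_rna_residue(name: str) -> bool:
    return name.upper() in _RNA_NAMES


def base_letter(name: str) -> str | None:
    """Collapse a residue name to its canonical base letter, if known."""
    name = name.upper()
    if name in {"A", "1MA", "A2M", "MIA", "MA6", "M7A"}:
        return "A"
    if name in {"G", "OMG", "2MG", "7MG", "M2G", "G7M"}:
        return "G"
    if name in {"C", "OMC", "5MC", "4OC"}:
        return "C"
    if name in {"U", "PSU", "5MU", "4SU", "H2U", "UR3"}:
        return "U"
    return None


# ---------------------------------------------------------------------------
# File I/O (gemmi-backed)

def read_structure(path: str | Path, model: int = 1, pdb_id: str | None = None) -> RibosomeStructure:
    """Read one model of an mmCIF or legacy PDB file.

    Raises :class:`StructureFormatError` for unparseable files and
    :class:`ModelNotFoundError` if the requested model is absent.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: file contains no models")

    chosen = None
    for mdl in st:
        if mdl.num == model:
            chosen = mdl
            break
    if chosen is None:
        raise ModelNotFoundError(
            f"{path}: model {model} not found (available: {[m.num for m in st]})"
        )

    atoms = []
    for chain in chosen:
        for res in chain:
            icode = res.seqid.icode.strip()
            for at in res:
                atoms.append(Atom(
                    chain.name, res.seqid.num, icode, res.name.strip(),
                    at.name, (at.pos.x, at.pos.y, at.pos.z),
                ))

    method_raw = st.info["_exptl.method"] if "_exptl.method" in st.info else ""
    method_raw = (method_raw or "").upper()
    if "X-RAY" in method_raw:
        method = "xray"
    elif "ELECTRON MICROSCOPY" in method_raw or "CRYO" in method_raw:
        method = "cryoem"
    else:
        method = "other"

    resolution = float(st.resolution) if st.resolution and st.resolution > 0 else None
    rs = RibosomeStructure(
        pdb_id=pdb_id or (st.name if st.name else path.stem),
        atoms=atoms, resolution=resolution, method=method, model_number=model,
    )
    rs.validate()
    return rs


def write_structure(rs: RibosomeStructure, path: str | Path) -> Path:
    """Write a structure as mmCIF (round-trippable through read_structure)."""
    import gemmi

    path = Path(path)
    st = gemmi.Structure()
    st.name = rs.pdb_id
    if rs.method == "xray":
        st.info["_exptl.method"] = "X-RAY DIFFRACTION"
    elif rs.method == "cryoem":
        st.info["_exptl.method"] = "ELECTRON MICROSCOPY"
    mdl = gemmi.Model(rs.model_number)
    chains: dict = {}
    for a in rs.atoms:
        key = (a.chain_id, a.residue_number, a.insertion_code)
        chains.setdefault(a.chain_id, {}).setdefault(key, []).append(a)
    for cid, residues in chains.items():
        chain = gemmi.Chain(cid)
        for (_, num, icode), res_atoms in sorted(residues.items(), key=lambda kv: (kv[0][1], kv[0][2])):
            res = gemmi.Residue()
            res.name = res_atoms[0].residue_name
            res.seqid = gemmi.SeqId(num, icode if icode else " ")
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.atom_name
                el = next((c for c in a.atom_name if c.isalpha()), "C")
                at.element = gemmi.Element(el)
                at.pos = gemmi.Position(*a.xyz)
                res.add_atom(at)
            chain.add_residue(res)
        mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    doc = st.make_mmcif_document()
    blk = doc.sole_block()
    if rs.resolution is not None:
        # gemmi recognises this tag on re-read regardless of method
        blk.set_pair("_em_3d_reconstruction.resolution", f"{rs.resolution:.2f}")
    doc.write_file(str(path))
    return path


def fetch_structure(pdb_id: str, dest_dir: str | Path,
                    url_template: str = "https://files.rcsb.org/download/{pdb_id}.cif") -> Path:
    """Download an mmCIF by accession into dest_dir (cached; not used in tests)."""
    import urllib.request

    dest = Path(dest_dir) / f"{pdb_id.lower()}.cif"
    if dest.exists():
        return dest
    dest.parent.mkdir(parents=True, exist_ok=True)
    urllib.request.urlretrieve(url_template.format(pdb_id=pdb_id.upper()), dest)
    return dest


# ---------------------------------------------------------------------------
# Chain identification

@dataclass
class ChainMap:
    """Assignment of functional chains in a ribosome complex.

    ``numbering_offset_16S`` shifts file numbering to E. coli numbering:
    ecoli_number = file_number - offset.
    """

    rrna16S: str | None
    mrna: str | None
    rrna23S: str | None = None
    trnas: list = field(default_factory=list)  # (chain_id, site label)
    numbering_offset_16S: int = 0

    def file_number_16S(self, ecoli_number: int) -> int:
        return ecoli_number + self.numbering_offset_16S


def _rna_chain_lengths(s: RibosomeStructure) -> dict:
    out = {}
    for cid in s.chain_ids():
        keys = s.chain_residues(cid)
        n_rna = sum(1 for k in keys if is_rna_residue(s.index[cid][k]["name"]))
        if keys and n_rna >= max(2, len(keys) // 2):
            out[cid] = len(keys)
    return out


def identify_chains(s: RibosomeStructure, hints: Mapping | None = None) -> ChainMap:
    """Assign 16S/23S/mRNA/tRNA chains by length heuristics.

    Explicit ``hints`` (keys rrna16S, rrna23S, mrna, trnas,
    numbering_offset_16S) override every heuristic. Ambiguities without
    hints raise :class:`ChainUnresolvedError` listing the candidates.
    """
    hints = dict(hints or {})
    lengths = _rna_chain_lengths(s)
    if len(lengths) < 2 and not ({"rrna16S", "mrna"} <= set(hints)):
        raise ChainUnresolvedError(
            f"{s.pdb_id}: fewer than two nucleic-acid chains found", list(lengths)
        )

    def pick(role: str, lo: int, hi: int) -> str | None:
        if role in hints:
            return hints[role]
        cands = [c for c, n in lengths.items() if lo <= n <= hi]
        if not cands:
            return None
        return max(cands, key=lambda c: lengths[c])

    c16 = pick("rrna16S", 1400, 1700)
    c23 = pick("rrna23S", 2700, 3100)

    trna_cands = hints.get("trnas")
    if trna_cands is None:
        trna_cands = [(c, "unknown") for c, n in sorted(lengths.items())
                      if 55 <= n <= 110 and c not in (c16, c23)]
    else:
        trna_cands = [(c, site) for c, site in
                      (t if isinstance(t, (tuple, list)) else (t, "unknown") for t in trna_cands)]

    if "mrna" in hints:
        cm_mrna = hints["mrna"]
    else:
        trna_ids = {c for c, _ in trna_cands}
        mrna_cands = [c for c, n in lengths.items()
                      if n < 55 and c not in (c16, c23) and c not in trna_ids]
        if len(mrna_cands) == 1:
            cm_mrna = mrna_cands[0]
        elif len(mrna_cands) > 1 and c16 is not None:
            cm_mrna = _nearest_to_decoding_site(s, c16, mrna_cands,
                                                hints.get("numbering_offset_16S", 0))
            if cm_mrna is None:
                raise ChainUnresolvedError(
                    f"{s.pdb_id}: ambiguous mRNA candidates", mrna_cands)
        elif len(mrna_cands) > 1:
            raise ChainUnresolvedError(
                f"{s.pdb_id}: ambiguous mRNA candidates and no 16S to disambiguate",
                mrna_cands)
        else:
            cm_mrna = None

    if c16 is None or cm_mrna is None:
        missing = [r for r, v in (("16S", c16), ("mRNA", cm_mrna)) if v is None]
        raise ChainUnresolvedError(
            f"{s.pdb_id}: could not assign {'/'.join(missing)} "
            f"(RNA chain lengths: {lengths})", list(lengths))
    if c16 == cm_mrna:
        raise ChainUnresolvedError(f"{s.pdb_id}: 16S and mRNA resolve to the same chain")

    return ChainMap(
        rrna16S=c16, rrna23S=c23, mrna=cm_mrna, trnas=trna_cands,
        numbering_offset_16S=int(hints.get("numbering_offset_16S", 0)),
    )


def _nearest_to_decoding_site(s: RibosomeStructure, c16: str,
                              candidates: Sequence, offset: int) -> str | None:
    """Pick the candidate chain closest to the 16S 1490-1510 region.

    Returns None when the decoding region is absent or the two nearest
    candidates are within 5 A of each other (genuinely ambiguous).
    """
    ref_pts = []
    for num in range(1490 + offset, 1511 + offset):
        ref_pts.extend(s.residue_atoms(c16, num).values())
    if not ref_pts:
        return None
    ref = np.array(ref_pts)
    dists = []
    for c in candidates:
        pts = np.array([a.xyz for a in s.atoms if a.chain_id == c])
        d = np.sqrt(((pts[:, None, :] - ref[None, :, :]) ** 2).sum(-1)).min()
        dists.append((d, c))
    dists.sort()
    if dists[0][0] > 30.0 or (len(dists) > 1 and dists[1][0] - dists[0][0] < 5.0):
        return None
    return dists[0][1]


# ---------------------------------------------------------------------------
# mRNA register

@dataclass
class MRNARegister:
    """Map between mRNA paper-convention positions and chain residues.

    Position +1 is the first base of the P-site codon; position 0 does not
    exist. ``direction`` is the residue-number increment per step 5'->3'.
    """

    chain_id: str
    p_codon_start: int  # residue number of position +1
    direction: int = 1
    resolvable_range: tuple | None = None
    p_trna_chain: str | None = None

    def residue_number(self, position: int) -> int:
        if position == 0:
            raise ValueError("mRNA register has no position 0")
        offset = position - 1 if position > 0 else position
        return self.p_codon_start + self.direction * offset

    def position_of(self, residue_number: int) -> int:
        steps = (residue_number - self.p_codon_start) * self.direction
        return steps + 1 if steps >= 0 else steps


def _min_wc_edge_distance(atoms_a: dict, name_a: str, atoms_b: dict, name_b: str) -> float:
    la, lb = base_letter(name_a), base_letter(name_b)
    ea = [atoms_a[n] for n in _WC_EDGE.get(la, ()) if n in atoms_a] if la else []
    eb = [atoms_b[n] for n in _WC_EDGE.get(lb, ()) if n in atoms_b] if lb else []
    if not ea:  # fall back to all base atoms
        ea = list(atoms_a.values())
    if not eb:
        eb = list(atoms_b.values())
    if not ea or not eb:
        return np.inf
    A, B = np.array(ea), np.array(eb)
    return float(np.sqrt(((A[:, None] - B[None, :]) ** 2).sum(-1)).min())


def locate_p_codon(s: RibosomeStructure, cm: ChainMap,
                   pairing_cutoff: float = 3.5,
                   p_codon_start: int | None = None,
                   direction: int = 1) -> MRNARegister:
    """Find the P-site codon by codon:anticodon pairing geometry.

    The P codon is the mRNA triplet whose three bases each make a
    Watson-Crick-edge contact of <= ``pairing_cutoff`` (A) with the
    anticodon triplet (residues 34-36) of a tRNA, paired antiparallel
    (codon position +1 pairs anticodon 36). When several tRNAs qualify the
    codon nearest the 5' end is chosen. An explicit ``p_codon_start``
    short-circuits detection entirely.
    """
    mrna_keys = s.chain_residues(cm.mrna)
    if p_codon_start is not None:
        rng = _resolvable_range(mrna_keys, p_codon_start, direction)
        return MRNARegister(cm.mrna, int(p_codon_start), direction, rng)

    if not cm.trnas:
        raise RegisterUnresolvedError(
            f"{s.pdb_id}: no tRNA chains available and no explicit p_codon_start")

    mrna_nums = [k[0] for k in mrna_keys if k[1] == ""]
    candidates = []  # (start_resnum, trna_chain): best window per tRNA
    for trna_chain, _site in cm.trnas:
        anticodon = {}
        for num in (34, 35, 36):
            atoms = s.residue_atoms(trna_chain, num)
            if atoms:
                anticodon[num] = (atoms, s.residue_name(trna_chain, num) or "")
        if len(anticodon) < 3:
            continue
        windows = []  # (total distance, start)
        for start in mrna_nums:
            triplet = [start + direction * i for i in range(3)]
            if not all(t in mrna_nums for t in triplet):
                continue
            total = 0.0
            for i, mnum in enumerate(triplet):  # codon i pairs anticodon 36-i
                m_atoms = s.residue_atoms(cm.mrna, mnum)
                m_name = s.residue_name(cm.mrna, mnum) or ""
                t_atoms, t_name = anticodon[36 - i]
                d = _min_wc_edge_distance(m_atoms, m_name, t_atoms, t_name)
                if d > pairing_cutoff:
                    total = np.inf
                    break
                total += d
            if np.isfinite(total):
                windows.append((total, start))
        if windows:  # tightest-pairing window of this tRNA
            candidates.append((min(windows)[1], trna_chain))

    if not candidates:
        raise RegisterUnresolvedError(
            f"{s.pdb_id}: no mRNA triplet pairs with any tRNA anticodon "
            f"within {pairing_cutoff} A")

    # choose the codon nearest the 5' (Shine-Dalgarno-proximal) end
    start, trna_chain = min(candidates, key=lambda c: direction * c[0])
    rng = _resolvable_range(mrna_keys, start, direction)
    return MRNARegister(cm.mrna, start, direction, rng, p_trna_chain=trna_chain)


def _resolvable_range(mrna_keys: Iterable, start: int, direction: int) -> tuple:
    nums = [k[0] for k in mrna_keys]
    if not nums:
        raise RegisterUnresolvedError("mRNA chain has no residues")
    positions = []
    for n in nums:
        steps = (n - start) * direction
        positions.append(steps + 1 if steps >= 0 else steps)
    return (min(positions), max(positions))
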