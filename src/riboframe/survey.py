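"""Batch survey: per-structure pipeline, confidence filter, aggregation.

Runs read -> chain identification -> mRNA register -> A1503 contact call
(optionally C1397 vs downstream positions) -> rotation-state call over an
accession list, applies a declared confidence filter, and aggregates
counts per conformational state (intercalated / stacked / retracted) in
the shape of a per-state summary table plus a body-vs-head rotation
scatter export.

The confidence filter is a codified stand-in for per-structure map-quality
judgement: reported resolution <= r_max, the register resolved, and the
query plus mRNA positions -4..+1 each with >= 5 ring atoms. Per-structure
failures are recorded, never fatal to the batch; the full threshold set is
embedded in every report so each count is reproducible from the report
alone.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import structure_io
from .errors import EmptySurveyError, RiboframeError
from .geometry import ContactCall, ContactThresholds, base_geometry, classify_contact
from .rotation import (DomainDefinition, StateWindows, classify_state,
                       measure_rotations)
from .structure_io import ChainMap, MRNARegister, RibosomeStructure

STATES = ("classical", "hybrid", "chimeric_hybrid")
A1503 = 1503
C1397 = 1397
CONTACT_POSITIONS = tuple(p for p in range(-4, 5) if p != 0)
C1397_POSITIONS = (7, 8, 9, 10)
FILTER_POSITIONS = (-4, -3, -2, -1, 1)


@dataclass
class SurveyConfig:
    """Batch configuration: file locations, thresholds, per-id overrides."""

    structure_dir: Path | None = None
    reference_path: Path | None = None     # classical-state reference
    reference_id: str | None = None
    thresholds: ContactThresholds = field(default_factory=ContactThresholds)
    windows: StateWindows = field(default_factory=StateWindows)
    domains: DomainDefinition = field(default_factory=DomainDefinition)
    r_max: float = 4.0                      # A, confidence resolution cutoff
    pairing_cutoff: float = 3.5             # A, codon:anticodon contact
    include_c1397: bool = False
    per_structure: dict = field(default_factory=dict)  # id -> overrides

    def path_for(self, pdb_id: str) -> Path:
        over = self.per_structure.get(pdb_id, {})
        if "path" in over:
            return Path(over["path"])
        if self.structure_dir is None:
            raise RiboframeError(f"no structure path configured for {pdb_id}")
        for ext in (".cif", ".pdb", ".cif.gz"):
            p = Path(self.structure_dir) / f"{pdb_id.lower()}{ext}"
            if p.exists():
                return p
        raise RiboframeError(f"{pdb_id}: no coordinate file under {self.structure_dir}")

    def provenance_hash(self) -> str:
        blob = json.dumps({
            "thresholds": vars(self.thresholds),
            "windows": {k: list(v) if isinstance(v, tuple) else v
                        for k, v in vars(self.windows).items()},
            "r_max": self.r_max,
            "pairing_cutoff": self.pairing_cutoff,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        if "structure_dir" in raw:
            kw["structure_dir"] = Path(raw["structure_dir"])
        if "reference_path" in raw:
            kw["reference_path"] = Path(raw["reference_path"])
        kw["reference_id"] = raw.get("reference_id")
        if "thresholds" in raw:
            kw["thresholds"] = ContactThresholds(**raw["thresholds"])
        if "windows" in raw:
            kw["windows"] = StateWindows(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["windows"].items()})
        for key in ("r_max", "pairing_cutoff", "include_c1397"):
            if key in raw:
                kw[key] = raw[key]
        kw["per_structure"] = raw.get("structures", {})
        return cls(**kw)


@dataclass
class ConfidenceResult:
    passed: bool
    reason: str | None = None

    def __str__(self):
        return "pass" if self.passed else f"fail({self.reason})"


@dataclass
class SurveyRecord:
    pdb_id: str
    confidence: ConfidenceResult
    state: str | None = None
    contact: ContactCall | None = None
    c1397_contact: ContactCall | None = None
    body_angle: float | None = None
    head_angle: float | None = None
    provenance: str = ""

    @property
    def intercalation_positions(self) -> str:
        """Partner pair in the survey's convention, codon-proximal first
        (e.g. "-1|-2")."""
        if self.contact and self.contact.call == "intercalated":
            return "|".join(str(p) for p in
                            sorted(self.contact.partners, reverse=True))
        return ""


# ---------------------------------------------------------------------------

def confidence_filter(s: RibosomeStructure, cm: ChainMap,
                      register: MRNARegister | None,
                      r_max: float = 4.0) -> ConfidenceResult:
    """Declared heuristic stand-in for map-quality screening."""
    if s.resolution is None:
        return ConfidenceResult(False, "resolution_missing")
    if s.resolution > r_max:
        return ConfidenceResult(False, "resolution")
    if register is None:
        return ConfidenceResult(False, "register_unresolved")
    if not _has_ring_atoms(s, cm.rrna16S, cm.file_number_16S(A1503)):
        return ConfidenceResult(False, "a1503_incomplete")
    for pos in FILTER_POSITIONS:
        if not _has_ring_atoms(s, register.chain_id, register.residue_number(pos)):
            return ConfidenceResult(False, "mrna_incomplete")
    return ConfidenceResult(True)


def _has_ring_atoms(s: RibosomeStructure, chain: str, resnum: int,
                    minimum: int = 5) -> bool:
    from .geometry import PURINE_RING, PYRIMIDINE_RING

    atoms = s.residue_atoms(chain, resnum)
    n = sum(1 for a in PURINE_RING if a in atoms)
    n_pyr = sum(1 for a in PYRIMIDINE_RING if a in atoms)
    return max(n, n_pyr) >= minimum


def contact_for_query(s: RibosomeStructure, cm: ChainMap, register: MRNARegister,
                      query_ecoli: int, positions=CONTACT_POSITIONS,
                      thresholds: ContactThresholds | None = None) -> ContactCall:
    """Contact call for a 16S base (E. coli numbering) against mRNA positions."""
    th = thresholds or ContactThresholds()
    try:
        q = base_geometry(s, cm.rrna16S, cm.file_number_16S(query_ecoli))
    except RiboframeError:
        return ContactCall("unresolved", warnings=("query_geometry",), thresholds=th)
    mrna = []
    prev_centroid = None
    for pos in positions:
        resnum = register.residue_number(pos)
        try:
            g = base_geometry(s, register.chain_id, resnum,
                              five_prime_centroid=prev_centroid)
            prev_centroid = g.centroid
        except RiboframeError:
            g = None
        mrna.append((pos, g))
    return classify_contact(q, mrna, th)


def survey_one(pdb_id: str, config: SurveyConfig,
               reference: RibosomeStructure | None = None,
               cm_ref: ChainMap | None = None,
               structure: RibosomeStructure | None = None) -> SurveyRecord:
    """Run the full per-structure pipeline; failures become fail records."""
    prov = config.provenance_hash()
    over = config.per_structure.get(pdb_id, {})
    try:
        s = structure if structure is not None else structure_io.read_structure(
            config.path_for(pdb_id), model=over.get("model", 1), pdb_id=pdb_id)
        cm = structure_io.identify_chains(s, hints=over.get("chains") or over)
        try:
            register = structure_io.locate_p_codon(
                s, cm, pairing_cutoff=config.pairing_cutoff,
                p_codon_start=over.get("p_codon_start"))
        except RiboframeError:
            register = None
        conf = confidence_filter(s, cm, register, config.r_max)
        rec = SurveyRecord(pdb_id, conf, provenance=prov)
        if not conf.passed:
            return rec
        rec.contact = contact_for_query(s, cm, register, A1503,
                                        thresholds=config.thresholds)
        if config.include_c1397:
            rec.c1397_contact = contact_for_query(
                s, cm, register, C1397, positions=C1397_POSITIONS,
                thresholds=config.thresholds)
        if reference is not None:
            m = measure_rotations(s, reference, cm, cm_ref or cm, config.domains)
            rec.body_angle, rec.head_angle = m.body_angle, m.head_angle
            rec.state = classify_state(m, config.windows).state
        return rec
    except RiboframeError as exc:
        return SurveyRecord(pdb_id,
                            ConfidenceResult(False, f"{type(exc).__name__}: {exc}"),
                            provenance=prov)


def run_survey(ids, config: SurveyConfig, structures: dict | None = None,
               reference: RibosomeStructure | None = None,
               cm_ref: ChainMap | None = None) -> list:
    """Survey an accession list; deterministic given inputs and config.

    ``structures`` optionally maps id -> RibosomeStructure (already in
    memory, e.g. synthetic fixtures); otherwise files are read from the
    configured directory. The classical-state reference for rotation is
    loaded once from config unless passed in.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("empty accession list")
    if reference is None and config.reference_path is not None:
        reference = structure_io.read_structure(config.reference_path,
                                                pdb_id=config.reference_id or "REF")
    if reference is not None and cm_ref is None:
        ref_over = config.per_structure.get(config.reference_id or "", {})
        cm_ref = structure_io.identify_chains(reference,
                                              hints=ref_over.get("chains") or ref_over)
    records = []
    for pdb_id in ids:
        s = structures.get(pdb_id) if structures else None
        records.append(survey_one(pdb_id, config, reference, cm_ref, structure=s))
    return records


# ---------------------------------------------------------------------------
# Aggregation (per-state summary table)

def aggregate(records) -> pd.DataFrame:
    """Per-state counts of contact classes plus percentages.

    Rows: classical, hybrid, chimeric_hybrid. A footer-style dict of
    excluded tallies is attached as ``df.attrs``. Raises
    :class:`EmptySurveyError` when no record passed the filter.
    """
    passing = [r for r in records if r.confidence.passed]
    if not passing:
        raise EmptySurveyError("no passing records to aggregate")

    rows = []
    n_unassigned = sum(1 for r in passing if r.state == "unassigned")
    n_unres_contact = sum(1 for r in passing
                          if r.contact is not None and r.contact.call == "unresolved")
    for state in STATES:
        recs = [r for r in passing if r.state == state
                and r.contact is not None and r.contact.call != "unresolved"]
        n = len(recs)
        n_int = sum(1 for r in recs if r.contact.call == "intercalated")
        n_stk = sum(1 for r in recs if r.contact.call == "stacked")
        n_ret = sum(1 for r in recs if r.contact.call == "retracted")
        pairs = [r.intercalation_positions for r in recs if r.intercalation_positions]
        modal = max(set(pairs), key=pairs.count) if pairs else ""
        pct = lambda k: round(100.0 * k / n) if n else 0
        rows.append({
            "state": state, "total": n,
            "n_intercalated": n_int, "positions": modal, "pct_intercalated": pct(n_int),
            "n_stacked": n_stk, "pct_stacked": pct(n_stk),
            "n_retracted": n_ret, "pct_retracted": pct(n_ret),
        })
    df = pd.DataFrame(rows).set_index("state")
    df.attrs["n_failed"] = sum(1 for r in records if not r.confidence.passed)
    df.attrs["n_unassigned_state"] = n_unassigned
    df.attrs["n_unresolved_contact"] = n_unres_contact
    df.attrs["provenance"] = passing[0].provenance
    return df


def records_frame(records) -> pd.DataFrame:
    """Flat per-structure report (one row per record)."""
    rows = []
    for r in records:
        rows.append({
            "pdb_id": r.pdb_id,
            "confidence": str(r.confidence),
            "state": r.state or "",
            "contact": r.contact.call if r.contact else "",
            "partners": r.intercalation_positions or (
                "|".join(str(p) for p in r.contact.partners) if r.contact else ""),
            "body_angle_deg": "" if r.body_angle is None else round(r.body_angle, 2),
            "head_angle_deg": "" if r.head_angle is None else round(r.head_angle, 2),
            "provenance": r.provenance,
        })
    return pd.DataFrame(rows)


def scatter_frame(records) -> pd.DataFrame:
    """Body-vs-head rotation scatter export (one point per passing record)."""
    rows = [{"pdb_id": r.pdb_id, "body_angle_deg": r.body_angle,
             "head_angle_deg": r.head_angle, "state": r.state,
             "contact": r.contact.call if r.contact else ""}
            for r in records
            if r.confidence.passed and r.body_angle is not None]
    return pd.DataFrame(rows)


def write_reports(records, out_dir: str | Path) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    records_frame(records).to_csv(out / "records.tsv", sep="\t", index=False)
    paths["records"] = out / "records.tsv"
    try:
        table = aggregate(records)
        table.to_csv(out / "table1.tsv", sep="\t")
        paths["table1"] = out / "table1.tsv"
    except EmptySurveyError:
        pass
    sc = scatter_frame(records)
    if len(sc):
        sc.to_csv(out / "fig2_scatter.csv", index=False)
        paths["scatter"] = out / "fig2_scatter.csv"
    return paths
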