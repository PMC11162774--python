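"""Quantification arithmetic for the -1 frameshift reporter assay.

The assay translates a reporter mRNA whose products are [35S]-Met labeled:
a full-length 27 kDa protein (0 frame) and a truncated 16 kDa premature
termination product from a -1 frameshift at an engineered slippery
sequence. Band intensities are proportional to the number of labeled
methionines, so each band is normalized by the internal methionine count
of its predicted product before any comparison:

    amount = intensity / n_internal_met
    percent_fs = 100 * fs / (fs + full)
    ratio_fs   = fs / full            (identically percent/(100-percent))
    activity   = (full + fs) / (full + fs) of the control lane

"Internal" methionines exclude only the initiator (position 1).
Replicates are summarized as mean +- SEM (sample sd / sqrt(N)); ratios are
averaged per replicate, not recomputed from mean percents — the two differ
whenever replicates vary.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class LaneQuant:
    """Background-corrected band intensities of one gel lane."""

    construct: str
    intensity_full: float   # 27 kDa full-length product, arbitrary units
    intensity_fs: float     # 16 kDa -1-frameshift product
    n_met_full: int         # internal methionines of the full-length product
    n_met_fs: int

    def __post_init__(self):
        if not (math.isfinite(self.intensity_full) and math.isfinite(self.intensity_fs)):
            raise ValueError("intensities must be finite")
        if self.intensity_full < 0 or self.intensity_fs < 0:
            raise ValueError("intensities must be >= 0")
        if self.n_met_full < 1 or self.n_met_fs < 1:
            raise ValueError("methionine counts must be >= 1")


@dataclass
class FrameshiftResult:
    construct: str
    percent_fs: list        # per replicate
    ratio_fs: list
    activity: list | None
    mean_percent: float
    sem_percent: float
    mean_ratio: float
    sem_ratio: float
    mean_activity: float | None = None
    sem_activity: float | None = None


def normalized_amounts(lane: LaneQuant) -> tuple:
    """Methionine-normalized product amounts (full-length, frameshift)."""
    return (lane.intensity_full / lane.n_met_full,
            lane.intensity_fs / lane.n_met_fs)


def frameshift_stats(amount_full: float, amount_fs: float) -> tuple:
    """(percent of total product in the -1 frame, -1/0-frame ratio)."""
    total = amount_full + amount_fs
    if total <= 0:
        raise ValueError("total product is zero; frameshift undefined")
    percent = 100.0 * amount_fs / total
    ratio = amount_fs / amount_full if amount_full > 0 else math.inf
    return percent, ratio


def activity(lane: LaneQuant, control: LaneQuant) -> float:
    """Total product (full + fs) as a fraction of the control lane's."""
    cf, cs = normalized_amounts(control)
    if cf + cs <= 0:
        raise ValueError("control lane has zero total product")
    lf, ls = normalized_amounts(lane)
    return (lf + ls) / (cf + cs)


def count_internal_met(sequence: str) -> int:
    """Number of methionines excluding the initiator (position 1)."""
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"invalid amino-acid characters: {sorted(bad)}")
    return seq[1:].count("M")


def summarize(values) -> tuple:
    """(mean, SEM) of replicate values; SEM = sample sd / sqrt(N), N >= 2."""
    vals = np.asarray(list(values), float)
    if len(vals) < 2:
        raise ValueError("SEM undefined for fewer than 2 replicates")
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(len(vals)))


def ratio_from_percent(percent: float) -> float:
    """Per-replicate identity ratio = p / (100 - p)."""
    if not 0 <= percent < 100:
        raise ValueError("percent must lie in [0, 100)")
    return percent / (100.0 - percent)


# ---------------------------------------------------------------------------
# Tabular pipeline

def quantify_constructs(lanes: pd.DataFrame, met_counts: dict,
                        control: str) -> pd.DataFrame:
    """Summary table from a tidy lane table.

    ``lanes`` columns: construct, replicate, intensity_full, intensity_fs.
    ``met_counts`` maps construct -> (n_met_full, n_met_fs). Activities are
    computed replicate-wise against the same replicate of ``control``.
    Output is shaped like the assay's summary table: one row per
    construct with percent, ratio and activity as mean +- SEM.
    """
    required = {"construct", "replicate", "intensity_full", "intensity_fs"}
    if not required <= set(lanes.columns):
        raise ValueError(f"lane table must have columns {sorted(required)}")

    def lane_of(row) -> LaneQuant:
        nf, ns = met_counts[row.construct]
        return LaneQuant(row.construct, float(row.intensity_full),
                         float(row.intensity_fs), nf, ns)

    control_by_rep = {row.replicate: lane_of(row)
                      for row in lanes[lanes.construct == control].itertuples()}
    rows = []
    for construct, grp in lanes.groupby("construct", sort=False):
        percents, ratios, acts = [], [], []
        for row in grp.itertuples():
            amounts = normalized_amounts(lane_of(row))
            p, r = frameshift_stats(*amounts)
            percents.append(p)
            ratios.append(r)
            if row.replicate in control_by_rep:
                acts.append(activity(lane_of(row), control_by_rep[row.replicate]))
        mp, sp = summarize(percents)
        mr, sr = summarize(ratios)
        ma, sa = summarize(acts) if len(acts) >= 2 else (None, None)
        rows.append({
            "construct": construct, "n": len(percents),
            "percent_fs": round(mp, 1), "percent_fs_sem": round(sp, 1),
            "ratio_fs": round(mr, 2), "ratio_fs_sem": round(sr, 2),
            "activity": None if ma is None else round(ma, 2),
            "activity_sem": None if sa is None else round(sa, 2),
        })
    return pd.DataFrame(rows).set_index("construct")


def read_lane_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def met_counts_from_fasta(path) -> dict:
    """Construct -> (n_met_full, n_met_fs) from a FASTA of product sequences.

    Records must be named ``<construct>|full`` and ``<construct>|fs``.
    """
    seqs = {}
    name = None
    chunks: list = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name:
        seqs[name] = "".join(chunks)
    out: dict = {}
    for key, seq in seqs.items():
        construct, _, product = key.partition("|")
        out.setdefault(construct, {})[product] = count_internal_met(seq)
    return {c: (d["full"], d["fs"]) for c, d in out.items()
            if "full" in d and "fs" in d}
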