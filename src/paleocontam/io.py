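"""Readers and writers for the site-count table, frequency panels, and a
simplified pileup-to-counts converter.

The on-disk site table is a self-describing tab-separated dialect: header
row, 1-based positions, explicit ancestral/derived alleles, one row per
site with columns

    chrom  pos  anc  der  a  d  w  y  [z]  [n_y  n_z]  is_transition  is_cpg

Load-time filtering drops sites that are non-segregating in the
contaminant (w in {0,1}) or anchor (y in {0,1}) panels and, when enabled,
CpG sites; dropped-row counts are reported by reason.  Defaults follow the
intended usage: filters (CpG exclusion, base quality >= 30) ON for
converter output from empirical data, OFF for synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .model import SiteData

logger = logging.getLogger("paleocontam")

__all__ = [
    "FilterReport",
    "read_site_table",
    "write_site_table",
    "read_panel",
    "pileup_to_counts",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

SITE_COLUMNS = ["chrom", "pos", "anc", "der", "a", "d", "w", "y"]
OPT_COLUMNS = ["z", "n_y", "n_z", "is_transition", "is_cpg"]


@dataclass
class FilterReport:
    rows_in: int = 0
    rows_kept: int = 0
    dropped: Dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str, n: int) -> None:
        if n:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(n)

    def check(self) -> None:
        assert self.rows_in == self.rows_kept + sum(self.dropped.values())


def read_site_table(path, exclude_cpg: bool = False
                    ) -> Tuple[SiteData, FilterReport]:
    """Load a site table, apply usability filters, and report drops."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col, lo in (("a", 0), ("d", 0)):
        if (df[col] < lo).any():
            bad = int(np.argmax(df[col].to_numpy() < lo)) + 2
            raise ValueError(f"{path}: negative count in column {col} (line {bad})")
    for col in ("w", "y"):
        v = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(v)) or np.any(v < 0) or np.any(v > 1):
            bad = int(np.argmax(~((v >= 0) & (v <= 1)))) + 2
            raise ValueError(f"{path}: frequency {col} outside [0, 1] (line {bad})")
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise ValueError(f"{path}: duplicate positions, first at line {int(np.argmax(dup.to_numpy())) + 2}")

    rep = FilterReport(rows_in=len(df))
    keep = np.ones(len(df), dtype=bool)
    for col, reason in (("w", "contaminant_panel_not_segregating"),
                        ("y", "anchor_panel_not_segregating")):
        bad = keep & ((df[col] <= 0.0) | (df[col] >= 1.0)).to_numpy()
        rep.drop(reason, bad.sum())
        keep &= ~bad
    if exclude_cpg and "is_cpg" in df.columns:
        bad = keep & df["is_cpg"].to_numpy(dtype=bool)
        rep.drop("cpg", bad.sum())
        keep &= ~bad
    df = df[keep]
    rep.rows_kept = len(df)
    rep.check()
    for reason, n in rep.dropped.items():
        logger.info("dropped %d rows: %s", n, reason)

    kw = {}
    if "n_y" in df.columns and "n_z" in df.columns and "z" in df.columns:
        kw["n_y"] = int(df["n_y"].iloc[0]) if len(df) else None
        kw["n_z"] = int(df["n_z"].iloc[0]) if len(df) else None
        if kw["n_y"]:
            kw["y_count"] = np.rint(df["y"].to_numpy() * kw["n_y"]).astype(np.int64)
            kw["z_count"] = np.rint(df["z"].to_numpy() * kw["n_z"]).astype(np.int64)
    data = SiteData(
        a=df["a"].to_numpy(), d=df["d"].to_numpy(),
        w=df["w"].to_numpy(dtype=float), y=df["y"].to_numpy(dtype=float),
        is_transition=df["is_transition"].to_numpy(dtype=bool)
        if "is_transition" in df.columns else None,
        is_cpg=df["is_cpg"].to_numpy(dtype=bool) if "is_cpg" in df.columns else None,
        chrom=df["chrom"].to_numpy(), pos=df["pos"].to_numpy(), **kw,
    )
    return data, rep


def write_site_table(data: SiteData, path, anc: Optional[Iterable[str]] = None,
                     der: Optional[Iterable[str]] = None) -> None:
    """Write a :class:`SiteData` in the native dialect.  Synthetic data
    without genomic coordinates gets a synthetic chrom/pos/allele framing."""
    n = len(data)
    df = pd.DataFrame({
        "chrom": data.chrom if data.chrom is not None else np.repeat("syn1", n),
        "pos": data.pos if data.pos is not None else np.arange(1, n + 1),
        "anc": list(anc) if anc is not None else np.repeat("A", n),
        "der": list(der) if der is not None else np.where(data.is_transition, "G", "C"),
        "a": data.a, "d": data.d, "w": data.w, "y": data.y,
    })
    if data.y_count is not None:
        df["z"] = data.z_count / data.n_z
        df["n_y"] = data.n_y
        df["n_z"] = data.n_z
    df["is_transition"] = data.is_transition
    df["is_cpg"] = data.is_cpg
    df.to_csv(path, sep="\t", index=False)


def read_panel(path) -> pd.DataFrame:
    """Frequency panel TSV: chrom, pos, anc, der, der_count, n_hap; adds a
    ``freq`` column."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = ["chrom", "pos", "anc", "der", "der_count", "n_hap"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing panel columns {missing}")
    df["freq"] = df["der_count"] / df["n_hap"]
    return df


# ---------------------------------------------------------------------------
# pileup conversion
# ---------------------------------------------------------------------------

def _parse_pileup_bases(bases: str, quals: str, ref: str, min_bq: int
                        ) -> Iterable[str]:
    """Yield called bases (uppercase) passing the base-quality threshold
    from one samtools-pileup base string."""
    out = []
    i = 0
    qi = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":            # read start: skip the mapping-quality char
            i += 2
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":           # indel: skip its length and sequence
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num)
            continue
        if c in ".,":
            base = ref.upper()
        elif c in "*<>":
            base = None
        else:
            base = c.upper()
        q = ord(quals[qi]) - 33 if qi < len(quals) else 0
        qi += 1
        i += 1
        if base is not None and q >= min_bq:
            out.append(base)
    return out


def pileup_to_counts(pileup_path, sites: pd.DataFrame, min_base_quality: int = 30,
                     exclude_cpg: bool = True) -> pd.DataFrame:
    """Convert a samtools text pileup into the native site table.

    ``sites`` is a panel-style frame with explicit ancestral/derived
    alleles and per-site frequencies (columns chrom, pos, anc, der, w, y
    [, z, n_y, n_z] [, is_cpg]); triallelic rows (anc == der or non-ACGT)
    are rejected.  Bases matching neither allele are discarded and
    counted.  Sites absent from the pileup get a = d = 0.
    """
    for col in ("chrom", "pos", "anc", "der", "w", "y"):
        if col not in sites.columns:
            raise ValueError(f"site list missing column {col}")
    anc_arr = sites["anc"].str.upper().to_numpy()
    der = sites["der"].str.upper().to_numpy()
    bad = (anc_arr == der) | ~np.isin(anc_arr, list("ACGT")) | ~np.isin(der, list("ACGT"))
    if bad.any():
        raise ValueError(f"site list has {bad.sum()} triallelic/invalid allele rows")

    index = {(str(c), int(p)): j for j, (c, p) in
             enumerate(zip(sites["chrom"], sites["pos"]))}
    a = np.zeros(len(sites), dtype=np.int64)
    d = np.zeros(len(sites), dtype=np.int64)
    other = 0
    seen_chroms = set()
    with open(pileup_path) as fh:
        for line_no, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{pileup_path}:{line_no}: not a 6-column pileup row")
            chrom, pos, ref, _depth, bases, quals = parts[:6]
            seen_chroms.add(chrom)
            j = index.get((chrom, int(pos)))
            if j is None:
                continue
            for base in _parse_pileup_bases(bases, quals, ref, min_base_quality):
                if base == anc_arr[j]:
                    a[j] += 1
                elif base == der[j]:
                    d[j] += 1
                else:
                    other += 1
    if seen_chroms and not seen_chroms & {str(c) for c in sites["chrom"]}:
        raise ValueError("pileup and site list share no chromosome names: "
                         "reference mismatch?")
    logger.info("pileup conversion: %d bases matched neither allele", other)

    out = sites.copy()
    out["a"] = a
    out["d"] = d
    out["is_transition"] = [
        (x, y) in _TRANSITIONS for x, y in zip(anc_arr, der)]
    if "is_cpg" not in out.columns:
        out["is_cpg"] = False
    if exclude_cpg:
        out = out[~out["is_cpg"].to_numpy(dtype=bool)]
    cols = SITE_COLUMNS + [c for c in OPT_COLUMNS if c in out.columns]
    return out[cols].reset_index(drop=True)
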