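"""Hairpin deconvolution: FASTQ reads -> hairpin x sample count matrix.

Each sequencing read from the PCR-amplified shRNA cassette contains the
hairpin's 21-nt target key embedded in constant vector flanks. Deconvolution
assigns a read to a hairpin iff exactly one library key occurs as an exact
substring of the read, on either strand; reads hitting zero or more than one
distinct key are counted as unassigned. Exact matching is the conservative,
auditable default; an optional 1-mismatch mode expands each key's Hamming
neighborhood (neighborhood collisions resolve to unassigned).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import SampleSheet, ShrnaLibrary, TARGET_LEN

__all__ = [
    "CountMatrix",
    "DeconvolutionError",
    "build_index",
    "count_sample",
    "count_samples",
    "representation_stats",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


class DeconvolutionError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class CountMatrix:
    """Integer hairpin x sample counts plus per-sample unassigned-read counts.

    The hairpin index always equals the full library hairpin set (zeros are
    kept — a dropout hairpin with no reads is data, not a missing row).
    """

    counts: pd.DataFrame  # hairpins x samples, int
    unassigned: pd.Series  # per sample
    sheet: SampleSheet

    def __post_init__(self):
        self.counts = self.counts.astype(np.int64)
        self.unassigned = self.unassigned.reindex(self.counts.columns).fillna(0).astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise DeconvolutionError("negative counts")
        sheet_ids = set(self.sheet.sample_ids)
        unknown = set(self.counts.columns) - sheet_ids
        if unknown:
            raise DeconvolutionError(f"samples not in sheet: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def hairpin_ids(self) -> list:
        return list(self.counts.index)

    def total_reads(self) -> pd.Series:
        """Assigned + unassigned reads per sample (conservation check input)."""
        return self.counts.sum(axis=0) + self.unassigned

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.loc["unassigned"] = self.unassigned
        out.to_csv(path, sep="\t", index_label="hairpin_id")

    @classmethod
    def read_tsv(cls, path, sheet: SampleSheet) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="hairpin_id")
        if "unassigned" in df.index:
            unassigned = df.loc["unassigned"]
            df = df.drop(index="unassigned")
        else:
            unassigned = pd.Series(0, index=df.columns)
        return cls(counts=df, unassigned=unassigned, sheet=sheet)


def build_index(lib: ShrnaLibrary, mismatches: int = 0) -> dict:
    """Exact-match index: 21-nt key (and its reverse complement) -> hairpin_id.

    With ``mismatches=1`` every single-substitution neighbor of each key is
    added; a neighbor claimed by two hairpins maps to None (ambiguous), so
    reads landing there go to unassigned. A collision between the primary
    keys of two hairpins is a library defect and raises at build time.
    """
    index: dict = {}
    for rec in lib.records:
        for key in {rec.target_seq, reverse_complement(rec.target_seq)}:
            prev = index.get(key)
            if prev is not None and prev != rec.hairpin_id:
                raise DeconvolutionError(
                    f"key collision: {prev!r} and {rec.hairpin_id!r} share key {key}"
                )
            index[key] = rec.hairpin_id
    if mismatches == 0:
        return index
    if mismatches != 1:
        raise DeconvolutionError("only 0 or 1 mismatches supported")
    neighbors: dict = {}
    for key, hid in index.items():
        for i in range(len(key)):
            for b in "ACGT":
                if b == key[i]:
                    continue
                nb = key[:i] + b + key[i + 1:]
                if nb in index:
                    continue  # exact keys always win
                if nb in neighbors and neighbors[nb] != hid:
                    neighbors[nb] = None  # ambiguous neighborhood
                else:
                    neighbors[nb] = hid
    merged = dict(neighbors)
    merged.update(index)
    return merged


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def count_sample(fastq_path, index: dict, k: int = TARGET_LEN):
    """Count hairpin keys in one FASTQ file.

    Returns ``(counts: dict hairpin_id -> int, unassigned: int, total: int)``.
    A read is assigned iff its k-mers hit exactly one distinct hairpin
    (ambiguous and key-less reads, and reads shorter than k, are unassigned).
    Conservation — assigned + unassigned == total — holds by construction and
    is re-asserted before returning.
    """
    counts: dict = {}
    unassigned = 0
    total = 0
    with _open_text(fastq_path) as fh:
        try:
            for _title, seq, _qual in FastqGeneralIterator(fh):
                total += 1
                seq = seq.upper()
                hit = None
                ambiguous = False
                for i in range(len(seq) - k + 1):
                    hid = index.get(seq[i : i + k])
                    if hid is None:
                        continue
                    if hit is None:
                        hit = hid
                    elif hid != hit:
                        ambiguous = True
                        break
                if hit is None or ambiguous:
                    unassigned += 1
                else:
                    counts[hit] = counts.get(hit, 0) + 1
        except ValueError as e:
            raise DeconvolutionError(
                f"{fastq_path}: malformed FASTQ near record {total + 1}: {e}"
            ) from None
    assert sum(counts.values()) + unassigned == total
    return counts, unassigned, total


def count_samples(
    fastq_paths: dict,
    lib: ShrnaLibrary,
    sheet: SampleSheet,
    mismatches: int = 0,
) -> CountMatrix:
    """Deconvolve several per-sample FASTQ files into one CountMatrix.

    ``fastq_paths`` maps sample_id -> FASTQ path (plain or .gz).
    """
    index = build_index(lib, mismatches=mismatches)
    hairpins = lib.hairpin_ids
    cols, un = {}, {}
    for sample_id, path in fastq_paths.items():
        if sample_id not in set(sheet.sample_ids):
            raise DeconvolutionError(f"unknown sample id {sample_id!r}")
        counts, unassigned, _total = count_sample(path, index)
        cols[sample_id] = pd.Series(counts, dtype=np.int64).reindex(hairpins).fillna(0)
        un[sample_id] = unassigned
    counts = pd.DataFrame(cols, index=pd.Index(hairpins, name="hairpin_id"))
    return CountMatrix(counts=counts, unassigned=pd.Series(un), sheet=sheet)


@dataclass
class RepresentationStats:
    """Library-representation QC: per-sample detection fractions and pairwise
    R^2 between log-transformed counts (transduction/engraftment QC)."""

    fraction_detected: pd.Series
    r_squared: pd.DataFrame  # columns: sample_a, sample_b, r_squared

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            self.fraction_detected.rename("fraction_detected").to_csv(
                fh, sep="\t", index_label="sample_id"
            )
            fh.write("\n")
            self.r_squared.to_csv(fh, sep="\t", index=False)


def representation_stats(
    cm: CountMatrix, pairs: list | None = None, pseudocount: float = 0.5
) -> RepresentationStats:
    """fraction_detected = share of library hairpins with >=1 read;
    r_squared = squared Pearson correlation of log2(count + pseudocount)."""
    frac = (cm.counts > 0).mean(axis=0)
    rows = []
    for a, b in pairs or []:
        for s in (a, b):
            if s not in cm.counts.columns:
                raise DeconvolutionError(f"unknown sample id {s!r}")
        la = np.log2(cm.counts[a].to_numpy() + pseudocount)
        lb = np.log2(cm.counts[b].to_numpy() + pseudocount)
        if np.std(la) == 0 or np.std(lb) == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(la, lb)[0, 1] ** 2)
        rows.append({"sample_a": a, "sample_b": b, "r_squared": r2})
    return RepresentationStats(
        fraction_detected=frac,
        r_squared=pd.DataFrame(rows, columns=["sample_a", "sample_b", "r_squared"]),
    )
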