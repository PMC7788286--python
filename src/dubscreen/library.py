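"""shRNA library and sample-sheet data model.

The unit of measurement in a pooled shRNA screen is the hairpin: a lentiviral
construct identified by the 21-nt sense sequence of its target site. Every
downstream stage (read deconvolution, differential abundance, hit-calling)
consumes the hairpin -> gene map defined here, together with a sample sheet
mapping sequencing samples to screen, recipient mouse and tissue.

Libraries and sample sheets are plain TSV files so they stay diffable and
interoperable with TRC-style vendor tables. Unknown columns are preserved on
round-trip but never interpreted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HairpinRecord",
    "ShrnaLibrary",
    "SampleSheet",
    "LibraryError",
    "load_library",
    "write_library",
    "load_sample_sheet",
    "write_sample_sheet",
    "split_pools",
    "make_dub_library",
]

VALID_POOLS = frozenset({"FULL", "DUB1", "DUB2"})
VALID_ROLES = frozenset({"test", "positive_control", "neutral_control"})
VALID_TISSUES = frozenset({"plasmid", "T0", "BM", "spleen"})
VALID_SAMPLE_ROLES = frozenset({"reference", "test"})
TARGET_LEN = 21
_DNA = frozenset("ACGT")

LIBRARY_COLUMNS = ["hairpin_id", "gene_symbol", "target_seq", "pools", "role"]
SHEET_COLUMNS = ["sample_id", "screen_id", "mouse_id", "tissue", "role"]


class LibraryError(ValueError):
    """Validation failure in a library or sample sheet."""


@dataclass(frozen=True)
class HairpinRecord:
    """One shRNA construct: id, targeted gene, 21-nt sense target sequence,
    pool membership and control role."""

    hairpin_id: str
    gene_symbol: str
    target_seq: str
    pools: frozenset = frozenset({"FULL"})
    role: str = "test"

    def __post_init__(self):
        object.__setattr__(self, "pools", frozenset(self.pools))
        if not self.hairpin_id:
            raise LibraryError("hairpin_id must be non-empty")
        if len(self.target_seq) != TARGET_LEN:
            raise LibraryError(
                f"hairpin {self.hairpin_id!r}: target_seq must be {TARGET_LEN} nt, "
                f"got {len(self.target_seq)}"
            )
        bad = set(self.target_seq) - _DNA
        if bad:
            raise LibraryError(
                f"hairpin {self.hairpin_id!r}: target_seq contains non-ACGT "
                f"characters {sorted(bad)}"
            )
        if not self.pools:
            raise LibraryError(f"hairpin {self.hairpin_id!r}: pools must be non-empty")
        unknown = self.pools - VALID_POOLS
        if unknown:
            raise LibraryError(
                f"hairpin {self.hairpin_id!r}: unknown pools {sorted(unknown)}"
            )
        if self.role not in VALID_ROLES:
            raise LibraryError(
                f"hairpin {self.hairpin_id!r}: role {self.role!r} not in "
                f"{sorted(VALID_ROLES)}"
            )


@dataclass
class ShrnaLibrary:
    """A validated collection of hairpin records.

    ``extra`` holds unknown TSV columns (indexed by hairpin_id) so vendor
    exports survive a load/write round-trip untouched.
    """

    records: list
    name: str = "library"
    extra: pd.DataFrame | None = None

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not self.records:
            raise LibraryError("no records")
        seen_ids, seen_seqs = {}, {}
        for rec in self.records:
            if rec.hairpin_id in seen_ids:
                raise LibraryError(f"duplicate hairpin_id {rec.hairpin_id!r}")
            if rec.target_seq in seen_seqs:
                raise LibraryError(
                    f"duplicate target_seq shared by {seen_seqs[rec.target_seq]!r} "
                    f"and {rec.hairpin_id!r}"
                )
            seen_ids[rec.hairpin_id] = rec
            seen_seqs[rec.target_seq] = rec.hairpin_id

    def __len__(self) -> int:
        return len(self.records)

    @property
    def hairpin_ids(self) -> list:
        return [r.hairpin_id for r in self.records]

    def genes(self, role: str | None = None) -> list:
        """Unique gene symbols, in first-appearance order, optionally by role."""
        out, seen = [], set()
        for r in self.records:
            if role is not None and r.role != role:
                continue
            if r.gene_symbol not in seen:
                seen.add(r.gene_symbol)
                out.append(r.gene_symbol)
        return out

    def records_for_gene(self, gene: str) -> list:
        return [r for r in self.records if r.gene_symbol == gene]

    @property
    def gene_of(self) -> dict:
        return {r.hairpin_id: r.gene_symbol for r in self.records}

    def hairpins_per_gene(self) -> pd.Series:
        counts = pd.Series([r.gene_symbol for r in self.records]).value_counts()
        counts.name = "n_hairpins"
        return counts

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "hairpin_id": [r.hairpin_id for r in self.records],
                "gene_symbol": [r.gene_symbol for r in self.records],
                "target_seq": [r.target_seq for r in self.records],
                "pools": [",".join(sorted(r.pools)) for r in self.records],
                "role": [r.role for r in self.records],
            }
        )
        if self.extra is not None and not self.extra.empty:
            df = df.join(self.extra.reset_index(drop=True))
        return df


def load_library(path, name: str | None = None) -> ShrnaLibrary:
    """Load and validate a library TSV (columns: hairpin_id, gene_symbol,
    target_seq, pools, role). Unknown columns are preserved but ignored.

    Raises :class:`LibraryError` naming the offending hairpin and TSV line on
    duplicate ids/sequences or malformed target sequences.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise LibraryError(f"{path}: no records (empty file)") from None
    if df.empty:
        raise LibraryError(f"{path}: no records")
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise LibraryError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # 1-based, after header
        try:
            records.append(
                HairpinRecord(
                    hairpin_id=str(row.hairpin_id),
                    gene_symbol=str(row.gene_symbol),
                    target_seq=str(row.target_seq).upper(),
                    pools=frozenset(str(row.pools).split(",")),
                    role=str(row.role),
                )
            )
        except LibraryError as e:
            raise LibraryError(f"{path} line {line_no}: {e}") from None
    extra_cols = [c for c in df.columns if c not in LIBRARY_COLUMNS]
    extra = df[extra_cols] if extra_cols else None
    return ShrnaLibrary(records=records, name=name or str(path), extra=extra)


def write_library(lib: ShrnaLibrary, path) -> None:
    lib.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class SampleSheet:
    """Sample metadata: sample_id -> (screen_id, mouse_id, tissue, role).

    Each screen must carry exactly one reference condition, the T0 input
    (the transduced cell population sampled immediately before injection).
    """

    table: pd.DataFrame

    def __post_init__(self):
        self.table = self.table.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise LibraryError(f"sample sheet missing columns {missing}")
        dup = self.table["sample_id"][self.table["sample_id"].duplicated()]
        if len(dup):
            raise LibraryError(f"duplicate sample_id {dup.iloc[0]!r}")
        bad_tissue = set(self.table["tissue"]) - VALID_TISSUES
        if bad_tissue:
            raise LibraryError(f"unknown tissue values {sorted(bad_tissue)}")
        bad_role = set(self.table["role"]) - VALID_SAMPLE_ROLES
        if bad_role:
            raise LibraryError(f"unknown sample roles {sorted(bad_role)}")
        for screen, grp in self.table.groupby("screen_id"):
            refs = grp[grp["role"] == "reference"]
            if len(refs) != 1:
                raise LibraryError(
                    f"screen {screen!r} must have exactly one reference (T0) "
                    f"sample, found {len(refs)}"
                )
            if refs["tissue"].iloc[0] != "T0":
                raise LibraryError(
                    f"screen {screen!r}: reference sample must have tissue T0"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.table["sample_id"])

    def screens(self) -> list:
        return list(dict.fromkeys(self.table["screen_id"]))

    def reference_sample(self, screen_id: str) -> str:
        grp = self.table[self.table["screen_id"] == screen_id]
        if grp.empty:
            raise LibraryError(f"unknown screen_id {screen_id!r}")
        return grp.loc[grp["role"] == "reference", "sample_id"].iloc[0]

    def samples(self, screen_id: str, tissue: str | None = None) -> list:
        grp = self.table[self.table["screen_id"] == screen_id]
        if grp.empty:
            raise LibraryError(f"unknown screen_id {screen_id!r}")
        if tissue is not None:
            grp = grp[grp["tissue"] == tissue]
        return list(grp["sample_id"])


def load_sample_sheet(path) -> SampleSheet:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise LibraryError(f"{path}: no records (empty file)") from None
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def split_pools(lib: ShrnaLibrary, assignment: dict):
    """Split a library into DUB1/DUB2 sub-pools by gene.

    ``assignment`` maps every test gene to "DUB1", "DUB2" or "both". Control
    hairpins (positive and neutral) are carried into both sub-pools so each
    screen retains its internal controls. Returns ``(dub1, dub2)``.
    """
    test_genes = set(lib.genes(role="test"))
    unassigned = test_genes - set(assignment)
    if unassigned:
        raise LibraryError(f"unassigned test genes: {sorted(unassigned)}")
    bad = {g: v for g, v in assignment.items() if v not in {"DUB1", "DUB2", "both"}}
    if bad:
        raise LibraryError(f"invalid pool assignments: {bad}")

    def _retag(rec: HairpinRecord, pool: str) -> HairpinRecord:
        return HairpinRecord(
            rec.hairpin_id, rec.gene_symbol, rec.target_seq,
            pools=rec.pools | {pool}, role=rec.role,
        )

    sub = {"DUB1": [], "DUB2": []}
    for rec in lib.records:
        if rec.role != "test":
            for pool in ("DUB1", "DUB2"):
                sub[pool].append(_retag(rec, pool))
            continue
        dest = assignment[rec.gene_symbol]
        for pool in ("DUB1", "DUB2") if dest == "both" else (dest,):
            sub[pool].append(_retag(rec, pool))
    return (
        ShrnaLibrary(sub["DUB1"], name=f"{lib.name}-DUB1"),
        ShrnaLibrary(sub["DUB2"], name=f"{lib.name}-DUB2"),
    )


# ---------------------------------------------------------------------------
# Packaged synthetic DUB-like library
# ---------------------------------------------------------------------------

# Mouse DUB-family gene symbols (USP, UCH, OTU, MJD/Josephin, JAMM and MINDY
# families) used to name the synthetic test genes. 99 symbols.
_DUB_GENES = [
    "Usp1", "Usp2", "Usp3", "Usp4", "Usp5", "Usp7", "Usp8", "Usp9x", "Usp9y",
    "Usp10", "Usp11", "Usp12", "Usp13", "Usp14", "Usp15", "Usp16", "Usp18",
    "Usp19", "Usp20", "Usp21", "Usp22", "Usp24", "Usp25", "Usp26", "Usp27x",
    "Usp28", "Usp29", "Usp30", "Usp31", "Usp32", "Usp33", "Usp34", "Usp35",
    "Usp36", "Usp37", "Usp38", "Usp39", "Usp40", "Usp42", "Usp43", "Usp44",
    "Usp45", "Usp46", "Usp47", "Usp48", "Usp49", "Usp50", "Usp51", "Usp53",
    "Usp54", "Uchl1", "Uchl3", "Uchl4", "Uchl5", "Bap1", "Otub1", "Otub2",
    "Otud1", "Otud3", "Otud4", "Otud5", "Otud6a", "Otud6b", "Otud7a", "Otud7b",
    "Yod1", "Zranb1", "Vcpip1", "Tnfaip3", "Cyld", "Alg13", "Josd1", "Josd2",
    "Atxn3", "Atxn3l", "Mysm1", "Brcc3", "Cops5", "Cops6", "Eif3f", "Eif3h",
    "Psmd7", "Psmd14", "Prpf8", "Mpnd", "Stambp", "Stambpl1", "Mindy1",
    "Mindy2", "Mindy3", "Mindy4", "Zufsp", "Usp17la", "Usp17lb", "Usp17lc",
    "Usp17ld", "Usp17le", "Dub1", "Dub2a",
]

# Control genes modeled on the screen design: known self-renewal regulators as
# dropout controls, a cell-cycle inhibitor as enrichment control, scramble as
# neutral.
_CONTROLS = [
    ("Bmi1", 4, "positive_control"),
    ("Brca1", 2, "positive_control"),
    ("Brca2", 2, "positive_control"),
    ("Cdkn1a", 2, "positive_control"),
    ("Scramble", 3, "neutral_control"),
]


def _random_kmers(n: int, k: int, rng: np.random.Generator) -> list:
    """n distinct k-mers, distinct also from each other's reverse complements."""
    comp = str.maketrans("ACGT", "TGCA")
    out, taken = [], set()
    bases = np.array(list("ACGT"))
    while len(out) < n:
        seq = "".join(bases[rng.integers(0, 4, size=k)])
        rc = seq.translate(comp)[::-1]
        if seq in taken or rc in taken:
            continue
        taken.add(seq)
        taken.add(rc)
        out.append(seq)
    return out


def make_dub_library(seed: int = 20508, name: str = "synthetic-dub-508") -> ShrnaLibrary:
    """The packaged synthetic 508-hairpin DUB-like library.

    99 test genes carry 3-6 hairpins each (495 test hairpins) and five control
    genes carry 13 hairpins, matching the shape of the screened library
    (~100 DUB genes, 3-6 hairpins per gene, 508 hairpins total). Target
    sequences are random distinct 21-mers; gene identities of the real library
    supplements are not reproduced. Test genes alternate between the DUB1 and
    DUB2 sub-pools; controls sit in both.
    """
    rng = np.random.default_rng(seed)
    # deterministic 3..6 pattern over 99 genes summing to 495
    per_gene = list(itertools.islice(itertools.cycle([3, 4, 5, 6, 6, 6]), 99))
    diff = 495 - sum(per_gene)
    step = 1 if diff > 0 else -1
    bound = 6 if diff > 0 else 3
    for i in range(len(per_gene)):
        if diff == 0:
            break
        if per_gene[i] * step < bound * step:
            per_gene[i] += step
            diff -= step
    assert sum(per_gene) == 495
    n_total = 495 + sum(n for _, n, _ in _CONTROLS)
    seqs = iter(_random_kmers(n_total, TARGET_LEN, rng))
    records = []
    for gi, (gene, n) in enumerate(zip(_DUB_GENES, per_gene)):
        pool = "DUB1" if gi % 2 == 0 else "DUB2"
        for j in range(n):
            records.append(
                HairpinRecord(
                    hairpin_id=f"sh{gene}_{j + 1}",
                    gene_symbol=gene,
                    target_seq=next(seqs),
                    pools=frozenset({"FULL", pool}),
                    role="test",
                )
            )
    for gene, n, role in _CONTROLS:
        for j in range(n):
            records.append(
                HairpinRecord(
                    hairpin_id=f"sh{gene}_{j + 1}",
                    gene_symbol=gene,
                    target_seq=next(seqs),
                    pools=frozenset({"FULL", "DUB1", "DUB2"}),
                    role=role,
                )
            )
    lib = ShrnaLibrary(records, name=name)
    assert len(lib) == 508
    return lib
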