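"""End-to-end synthetic generator for the in vivo pooled shRNA screen.

The generative model follows the transplantation design it emulates:

1. plasmid pool — hairpin proportions are log-normal (sd in log2 units),
   reflecting uneven pooled cloning;
2. T0 / input — a multinomial draw of the transduced cell population
   (default 1e6 cells at MOI < 1, so one hairpin per cell);
3. engraftment bottleneck — per recipient mouse, a multinomial draw of
   n_cells_transduced x engraftment_fraction cells from the T0 proportions
   (default 1e5 cells ~ 200-fold per-hairpin representation over 508
   hairpins, i.e. the "2,000-fold library representation" regime scaled by
   the engrafting fraction), the source of stochastic per-mouse drift;
4. selection — each hairpin's proportion is multiplied by
   2^(fitness x efficacy x weeks) and renormalized (fitness in log2 units
   per week; negative = dropout, positive = enrichment; per-hairpin efficacy
   in [0, 1] models knockdown-potency heterogeneity);
5. sequencing — a multinomial draw of reads_per_sample over proportions
   perturbed by per-hairpin log-normal PCR amplification factors.

All randomness flows from a single seed through named substreams, so any
sample can be regenerated independently and the whole screen is reproducible
byte-for-byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .deconvolve import CountMatrix
from .library import SampleSheet, ShrnaLibrary

__all__ = [
    "ScreenSimParams",
    "EffectModel",
    "TruthTable",
    "ScreenSimResult",
    "ReadLayout",
    "simulate_screen",
    "write_fastq",
    "substream",
]


def substream(seed: int, *labels) -> np.random.Generator:
    """Independent, reproducible RNG stream named by (seed, labels)."""
    key = tuple(zlib.crc32(str(x).encode()) for x in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


@dataclass
class ScreenSimParams:
    """Screen-scale parameters. Defaults are the primary-screen design point:
    ~1e6 transduced cells per mouse over a 508-hairpin library (~2,000-fold
    representation), 5 recipient mice, a 4-week in vivo window."""

    n_cells_transduced: int = 1_000_000
    moi: float = 0.3  # kept < 1 so each cell carries a single hairpin
    plasmid_abundance_sd: float = 0.5  # log2 units
    engraftment_fraction: float = 0.1
    n_mice: int = 5
    weeks: float = 4.0
    reads_per_sample: int = 2_000_000
    pcr_overdispersion: float = 0.25  # log-normal sd of per-hairpin PCR factor
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_transduced <= 0 or self.n_mice <= 0 or self.reads_per_sample <= 0:
            raise ValueError("counts must be positive")
        if not 0 < self.moi < 1:
            raise ValueError("moi must be in (0, 1)")
        if not 0 < self.engraftment_fraction <= 1:
            raise ValueError("engraftment_fraction must be in (0, 1]")
        if self.plasmid_abundance_sd < 0 or self.pcr_overdispersion < 0:
            raise ValueError("dispersions must be >= 0")
        if self.weeks <= 0:
            raise ValueError("weeks must be positive")


@dataclass
class EffectModel:
    """Planted fitness effects: per-gene log2 change in relative abundance per
    week (negative = dropout), scaled per hairpin by an efficacy in [0, 1]."""

    gene_fitness: dict = field(default_factory=dict)
    hairpin_efficacy: dict = field(default_factory=dict)

    @classmethod
    def neutral(cls, lib: ShrnaLibrary) -> "EffectModel":
        return cls(
            gene_fitness={g: 0.0 for g in lib.genes()},
            hairpin_efficacy={h: 1.0 for h in lib.hairpin_ids},
        )

    def with_gene(self, lib: ShrnaLibrary, gene: str, fitness: float,
                  efficacies=None) -> "EffectModel":
        """Return a copy with one gene's fitness (and optionally per-hairpin
        efficacies, in library order) replanted."""
        gf = dict(self.gene_fitness)
        he = dict(self.hairpin_efficacy)
        gf[gene] = fitness
        if efficacies is not None:
            recs = lib.records_for_gene(gene)
            if len(efficacies) != len(recs):
                raise ValueError(
                    f"{gene}: {len(recs)} hairpins but {len(efficacies)} efficacies"
                )
            for rec, e in zip(recs, efficacies):
                he[rec.hairpin_id] = float(e)
        return EffectModel(gf, he)

    def validate(self, lib: ShrnaLibrary) -> None:
        missing = set(lib.genes()) - set(self.gene_fitness)
        if missing:
            raise ValueError(f"genes without fitness effect: {sorted(missing)[:5]}")
        for h in lib.hairpin_ids:
            e = self.hairpin_efficacy.get(h, 1.0)
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"hairpin {h!r}: efficacy {e} outside [0, 1]")

    def per_hairpin_log2_per_week(self, lib: ShrnaLibrary) -> pd.Series:
        vals = {
            r.hairpin_id: self.gene_fitness[r.gene_symbol]
            * self.hairpin_efficacy.get(r.hairpin_id, 1.0)
            for r in lib.records
        }
        return pd.Series(vals).reindex(lib.hairpin_ids)

    def directions(self, lib: ShrnaLibrary) -> pd.Series:
        d = {}
        for g in lib.genes():
            f = self.gene_fitness[g]
            d[g] = "dropout" if f < 0 else ("enriched" if f > 0 else "neutral")
        return pd.Series(d, name="direction")


def planted_dropout_effects(
    lib: ShrnaLibrary,
    genes,
    fitness: float = -1.25,
    efficacies=(1.0, 0.8, 0.5, 0.3, 0.3, 0.3),
) -> EffectModel:
    """Neutral background plus planted dropout genes.

    Default fitness -1.25 log2/week over a 4-week screen is a 32-fold
    expected dropout at full efficacy; the default efficacy ladder makes the
    first two hairpins of each planted gene "effective" (>= 16-fold expected)
    and leaves the rest sub-threshold, mimicking knockdown-potency
    heterogeneity across a gene's hairpins.
    """
    effects = EffectModel.neutral(lib)
    for g in genes:
        recs = lib.records_for_gene(g)
        effects = effects.with_gene(lib, g, fitness, list(efficacies[: len(recs)]))
    return effects


@dataclass
class TruthTable:
    """Ground truth of one simulated screen: planted per-gene direction and
    magnitude, and the realized integer cell counts per hairpin at each
    cell-stage sample (T0 and per-mouse engraftment bottlenecks)."""

    gene_truth: pd.DataFrame  # gene x (direction, fitness_log2_per_week)
    cell_counts: pd.DataFrame  # hairpin x cell-stage sample

    def validate(self) -> None:
        if (self.cell_counts.to_numpy() < 0).any():
            raise ValueError("negative cell counts")


@dataclass
class ScreenSimResult:
    counts: CountMatrix
    sheet: SampleSheet
    truth: TruthTable
    screen_id: str


def _sequence(props: np.ndarray, reads: int, pcr_sd: float,
              rng: np.random.Generator) -> np.ndarray:
    """Read-level multinomial over proportions perturbed by per-hairpin
    log-normal PCR amplification factors."""
    if pcr_sd > 0:
        q = props * rng.lognormal(0.0, pcr_sd, size=props.size)
    else:
        q = props.copy()
    q /= q.sum()
    return rng.multinomial(reads, q)


def simulate_screen(
    lib: ShrnaLibrary,
    params: ScreenSimParams,
    effects: EffectModel | None = None,
    screen_id: str = "primary",
    spleen: bool = False,
) -> ScreenSimResult:
    """Simulate one screen: plasmid, T0 and per-mouse BM (optionally spleen)
    samples, returning sequencing counts, the sample sheet and the truth.

    Spleen samples are an independent second bottleneck from the same T0 with
    the same selection, supporting the BM-vs-spleen correlation QC.
    """
    params.validate()
    effects = effects or EffectModel.neutral(lib)
    effects.validate(lib)
    n = len(lib)
    hairpins = lib.hairpin_ids

    rng = substream(params.seed, screen_id, "plasmid")
    plasmid_props = np.power(2.0, rng.normal(0.0, params.plasmid_abundance_sd, n))
    plasmid_props /= plasmid_props.sum()
    plasmid_reads = _sequence(
        plasmid_props, params.reads_per_sample, params.pcr_overdispersion,
        substream(params.seed, screen_id, "plasmid", "seq"),
    )

    t0_cells = substream(params.seed, screen_id, "T0").multinomial(
        params.n_cells_transduced, plasmid_props
    )
    t0_props = t0_cells / t0_cells.sum()
    t0_reads = _sequence(
        t0_props, params.reads_per_sample, params.pcr_overdispersion,
        substream(params.seed, screen_id, "T0", "seq"),
    )

    growth = np.power(
        2.0, effects.per_hairpin_log2_per_week(lib).to_numpy() * params.weeks
    )
    n_engraft = max(1, int(round(params.n_cells_transduced * params.engraftment_fraction)))

    read_cols = {"plasmid": plasmid_reads, "T0": t0_reads}
    cell_cols = {"T0": t0_cells}
    rows = [
        {"sample_id": "plasmid", "screen_id": screen_id, "mouse_id": "pool",
         "tissue": "plasmid", "role": "test"},
        {"sample_id": "T0", "screen_id": screen_id, "mouse_id": "pool",
         "tissue": "T0", "role": "reference"},
    ]
    tissues = ["BM"] + (["spleen"] if spleen else [])
    for m in range(1, params.n_mice + 1):
        for tissue in tissues:
            sid = f"{tissue}_m{m}"
            # the bottleneck is a subset of the injected cells, so draw
            # without replacement; full engraftment is then the identity
            eng = substream(params.seed, screen_id, tissue, m, "engraft")\
                .multivariate_hypergeometric(t0_cells, n_engraft)
            props = eng.astype(float) * growth
            props /= props.sum()
            read_cols[sid] = _sequence(
                props, params.reads_per_sample, params.pcr_overdispersion,
                substream(params.seed, screen_id, tissue, m, "seq"),
            )
            cell_cols[sid] = eng
            rows.append(
                {"sample_id": sid, "screen_id": screen_id, "mouse_id": f"m{m}",
                 "tissue": tissue, "role": "test"}
            )

    idx = pd.Index(hairpins, name="hairpin_id")
    sheet = SampleSheet(pd.DataFrame(rows))
    counts = CountMatrix(
        counts=pd.DataFrame(read_cols, index=idx),
        unassigned=pd.Series(0, index=list(read_cols)),
        sheet=sheet,
    )
    gene_truth = pd.DataFrame(
        {
            "direction": effects.directions(lib),
            "fitness_log2_per_week": pd.Series(effects.gene_fitness),
        }
    )
    gene_truth.index.name = "gene_symbol"
    truth = TruthTable(gene_truth=gene_truth, cell_counts=pd.DataFrame(cell_cols, index=idx))
    truth.validate()
    return ScreenSimResult(counts=counts, sheet=sheet, truth=truth, screen_id=screen_id)


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadLayout:
    """Constant vector flanks around the 21-nt hairpin key. The key offset in
    every read equals ``len(flank5)``. Defaults give 50-nt reads resembling a
    single-end shRNA-cassette amplicon."""

    flank5: str = "TTTGTGGAAAGGACGAAA"  # 18 nt, U6-promoter-like
    flank3: str = "CTCGAGTTAAT"  # 11 nt, loop-side
    quality_char: str = "I"  # Phred+33 Q40


def write_fastq(
    counts,
    lib: ShrnaLibrary,
    path,
    layout: ReadLayout = ReadLayout(),
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> None:
    """Write one FASTQ file with ``counts[hairpin_id]`` reads per hairpin,
    each embedding the hairpin key inside the constant flanks.

    ``error_rate`` applies independent uniform base substitutions; reads with
    an error inside the key become unrecoverable under exact matching.
    Reads are emitted in hairpin order (interleaving carries no information
    for downstream counting).
    """
    counts = pd.Series(counts)
    if (counts < 0).any():
        raise ValueError("negative read counts")
    if error_rate < 0 or error_rate >= 1:
        raise ValueError("error_rate must be in [0, 1)")
    if error_rate > 0 and rng is None:
        raise ValueError("rng required when error_rate > 0")
    seq_of = {r.hairpin_id: r.target_seq for r in lib.records}
    # substitution alphabet excludes the original base, so the per-base
    # corruption probability is exactly error_rate
    others = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    with open(path, "w") as fh:
        for hid, n_reads in counts.items():
            if n_reads == 0:
                continue
            if hid not in seq_of:
                raise ValueError(f"unknown hairpin {hid!r}")
            read = layout.flank5 + seq_of[hid] + layout.flank3
            qual = layout.quality_char * len(read)
            for i in range(int(n_reads)):
                out = read
                if error_rate > 0:
                    hit = np.flatnonzero(rng.random(len(read)) < error_rate)
                    if hit.size:
                        chars = list(read)
                        for pos, pick in zip(hit, rng.integers(0, 3, size=hit.size)):
                            chars[pos] = others[chars[pos]][pick]
                        out = "".join(chars)
                fh.write(f"@{hid}:{i}\n{out}\n+\n{qual}\n")


def write_screen_fastq(
    result: ScreenSimResult,
    lib: ShrnaLibrary,
    outdir,
    layout: ReadLayout = ReadLayout(),
    error_rate: float = 0.0,
    seed: int = 0,
) -> dict:
    """Emit one FASTQ per sample of a simulated screen; returns sample->path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sid in result.counts.sample_ids:
        rng = substream(seed, result.screen_id, sid, "err")
        path = outdir / f"{sid}.fastq"
        write_fastq(
            result.counts.counts[sid], lib, path,
            layout=layout, error_rate=error_rate,
            rng=rng if error_rate > 0 else None,
        )
        paths[sid] = path
    return paths
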