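"""Deconvolution: exact-substring key matching, conservation, strand
symmetry, round-trip identity with the FASTQ writer, representation QC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dubscreen import (
    CountMatrix,
    HairpinRecord,
    ShrnaLibrary,
    build_index,
    count_sample,
    count_samples,
    representation_stats,
    simulate_screen,
    substream,
    write_fastq,
)
from dubscreen.deconvolve import DeconvolutionError, reverse_complement
from dubscreen.library import LibraryError
from dubscreen.simulate import ReadLayout, ScreenSimParams


def _write_reads(path, seqs):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s}\n+\n{'I' * len(s)}\n")


def test_index_self_hits_and_absent_key(tiny_lib):
    index = build_index(tiny_lib)
    for rec in tiny_lib.records:
        assert index[rec.target_seq] == rec.hairpin_id
        assert index[reverse_complement(rec.target_seq)] == rec.hairpin_id
    assert index.get("A" * 21) is None


def test_reverse_complement_collision_detected(tiny_lib):
    recs = list(tiny_lib.records)
    clash = HairpinRecord(
        "shClash_1", "GeneZ", reverse_complement(recs[0].target_seq)
    )
    lib = ShrnaLibrary(recs + [clash])  # sequences differ, so the library loads
    with pytest.raises(DeconvolutionError, match="collision"):
        build_index(lib)


def test_shared_target_seq_rejected_at_library_level(tiny_lib):
    recs = list(tiny_lib.records)
    with pytest.raises(LibraryError, match="duplicate target_seq"):
        ShrnaLibrary(recs + [HairpinRecord("shDup_1", "GeneZ", recs[0].target_seq)])


def test_read_assignment_rules(tiny_lib, tmp_path):
    index = build_index(tiny_lib)
    k1 = tiny_lib.records[0].target_seq
    k2 = tiny_lib.records[1].target_seq
    fq = tmp_path / "reads.fastq"
    _write_reads(
        fq,
        [
            "ACGT" + k1 + "TTTT",  # embedded key -> assigned
            k1 + k2,  # two distinct keys -> ambiguous, unassigned
            "A" * 40,  # no key -> unassigned
            "ACGTACGT",  # shorter than 21 nt -> unassigned
            "acgt" + reverse_complement(k1).lower() + "gg",  # opposite strand, lower case
        ],
    )
    counts, unassigned, total = count_sample(fq, index)
    assert total == 5
    assert counts == {tiny_lib.records[0].hairpin_id: 2}
    assert unassigned == 3


def test_malformed_fastq_reports_record(tiny_lib, tmp_path):
    fq = tmp_path / "bad.fastq"
    fq.write_text("@r0\nACGT\n+\nII\n")  # quality length mismatch
    with pytest.raises(DeconvolutionError, match="record 1"):
        count_sample(fq, build_index(tiny_lib))


def test_round_trip_identity_at_zero_error(tiny_lib, tmp_path):
    """count_sample(write_fastq(counts)) == counts, exactly."""
    rng = substream(11, "roundtrip")
    planted = pd.Series(
        rng.integers(0, 400, len(tiny_lib)), index=tiny_lib.hairpin_ids
    )
    fq = tmp_path / "sample.fastq"
    write_fastq(planted, tiny_lib, fq)
    counts, unassigned, total = count_sample(fq, build_index(tiny_lib))
    got = pd.Series(counts).reindex(tiny_lib.hairpin_ids).fillna(0).astype(int)
    assert got.equals(planted.astype(int))
    assert unassigned == 0
    assert total == planted.sum()


def test_strand_symmetry(tiny_lib, tmp_path):
    rng = substream(12, "strand")
    planted = pd.Series(
        rng.integers(0, 50, len(tiny_lib)), index=tiny_lib.hairpin_ids
    )
    fwd = tmp_path / "fwd.fastq"
    write_fastq(planted, tiny_lib, fwd)
    rev = tmp_path / "rev.fastq"
    seqs = [line for i, line in enumerate(fwd.read_text().splitlines()) if i % 4 == 1]
    _write_reads(rev, [reverse_complement(s) for s in seqs])
    index = build_index(tiny_lib)
    c_fwd, *_ = count_sample(fwd, index)
    c_rev, *_ = count_sample(rev, index)
    assert c_fwd == c_rev


def test_substitution_error_rate_matches_analytic_loss(tiny_lib, tmp_path):
    """With per-base error e, a read survives exact matching iff its 21-nt key
    is error-free: assigned fraction ~ Binomial(n, (1-e)^21)."""
    e = 0.01
    n_reads = 20_000
    hid = tiny_lib.hairpin_ids[0]
    fq = tmp_path / "err.fastq"
    write_fastq({hid: n_reads}, tiny_lib, fq, error_rate=e, rng=substream(13, "err"))
    counts, unassigned, total = count_sample(fq, build_index(tiny_lib))
    p_keep = (1 - e) ** 21
    se = np.sqrt(p_keep * (1 - p_keep) / n_reads)
    assert abs(counts.get(hid, 0) / total - p_keep) < 5 * se
    assert counts.get(hid, 0) + unassigned == total


def test_one_mismatch_mode_recovers_single_substitutions(tiny_lib, tmp_path):
    rec = tiny_lib.records[0]
    mutated = "G" + rec.target_seq[1:] if rec.target_seq[0] != "G" else "T" + rec.target_seq[1:]
    fq = tmp_path / "mm.fastq"
    _write_reads(fq, ["AC" + mutated + "GT"])
    exact, *_ = count_sample(fq, build_index(tiny_lib, mismatches=0))
    fuzzy, *_ = count_sample(fq, build_index(tiny_lib, mismatches=1))
    assert exact == {}
    assert fuzzy == {rec.hairpin_id: 1}


def test_count_samples_full_screen_round_trip(tiny_lib, tmp_path):
    """FASTQ emission + deconvolution of a whole simulated screen is the
    identity on the sequenced counts."""
    from dubscreen.simulate import write_screen_fastq

    params = ScreenSimParams(
        seed=5, n_cells_transduced=20_000, reads_per_sample=2_000, n_mice=2
    )
    res = simulate_screen(tiny_lib, params)
    paths = write_screen_fastq(res, tiny_lib, tmp_path / "fq")
    cm = count_samples(paths, tiny_lib, res.sheet)
    assert cm.counts.equals(res.counts.counts)
    assert (cm.unassigned == 0).all()
    assert (cm.total_reads() == params.reads_per_sample).all()


def test_representation_stats(tiny_lib):
    sheet_rows = [
        {"sample_id": s, "screen_id": "primary", "mouse_id": "pool",
         "tissue": t, "role": r}
        for s, t, r in [("T0", "T0", "reference"), ("BM_m1", "BM", "test")]
    ]
    from dubscreen import SampleSheet

    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    n = len(tiny_lib)
    rng = substream(14, "rep")
    full = pd.Series(rng.integers(1, 100, n), index=tiny_lib.hairpin_ids)
    partial = full.copy()
    partial.iloc[:3] = 0  # 3 of the 11 hairpins drop out entirely
    cm = CountMatrix(
        counts=pd.DataFrame({"T0": full, "BM_m1": partial}),
        unassigned=pd.Series(0, index=["T0", "BM_m1"]),
        sheet=sheet,
    )
    stats = representation_stats(cm, pairs=[("T0", "T0"), ("T0", "BM_m1")])
    assert stats.fraction_detected["T0"] == 1.0
    assert stats.fraction_detected["BM_m1"] == pytest.approx((n - 3) / n)
    r2 = stats.r_squared.set_index(["sample_a", "sample_b"])["r_squared"]
    assert r2[("T0", "T0")] == pytest.approx(1.0)
    assert 0.0 <= r2[("T0", "BM_m1")] <= 1.0
    with pytest.raises(DeconvolutionError, match="unknown sample"):
        representation_stats(cm, pairs=[("T0", "nope")])


def test_fraction_detected_constructed_count(lib508, neutral_screen):
    """457 of 508 hairpins detected -> fraction 457/508."""
    cm = neutral_screen.counts
    col = cm.counts["T0"].copy()
    col.iloc[:51] = 0  # knock out 51 hairpins
    cm2 = CountMatrix(
        counts=cm.counts.assign(T0=col), unassigned=cm.unassigned, sheet=cm.sheet
    )
    stats = representation_stats(cm2)
    assert stats.fraction_detected["T0"] == pytest.approx(457 / 508)


def test_count_matrix_tsv_round_trip(neutral_screen, tmp_path):
    path = tmp_path / "counts.tsv"
    neutral_screen.counts.write_tsv(path)
    back = CountMatrix.read_tsv(path, neutral_screen.sheet)
    assert back.counts.equals(neutral_screen.counts.counts)
    assert back.unassigned.equals(neutral_screen.counts.unassigned)
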