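"""Window counting, size factors, RE/RRO, metagene, and ratio summaries."""

import numpy as np
import pandas as pd
import pytest

from recseq.annotation_io import AlignedFootprint, TranscriptModel
from recseq.quantification import (
    build_count_table,
    count_windows,
    metagene,
    mrna_density,
    ratio_summaries,
    recruitment_efficiency,
    spike_in_size_factors,
)

from conftest import random_transcript


def brute_force_windows(p_sites, transcript):
    """Independent interval-membership oracle for the four windows."""
    m, stop = transcript.main_aug, transcript.stop_last
    return (
        sum(m - 3 <= p <= m + 6 for p in p_sites),
        sum(m + 9 <= p <= stop for p in p_sites),
        sum(0 <= p <= m - 5 for p in p_sites),
        sum(m <= p <= stop for p in p_sites),
    )


def make_transcript(utr5=100, cds=600):
    seq = "G" * utr5 + "ATG" + "C" * (cds - 6) + "TAA" + "G" * 50
    return TranscriptModel.from_annotation("t", seq, utr5, cds)


class TestCountWindows:
    def test_window_membership_example(self):
        t = make_transcript(utr5=100, cds=600)  # mAUG 100, stop_last 699
        p_sites = [95, 97, 100, 106, 107, 109, 699, 700]
        wc = count_windows(p_sites, t)
        assert wc.mRPF == 3  # 97, 100, 106
        assert wc.iRPF == 2  # 109, 699
        assert wc.uRPF == 1  # 95
        assert wc.cdsRPF == 5  # 100, 106, 107, 109, 699 — not 700
        assert (wc.mRPF, wc.iRPF, wc.uRPF, wc.cdsRPF) == brute_force_windows(p_sites, t)

    def test_no_reads(self):
        assert count_windows([], make_transcript()) == (0, 0, 0, 0)

    def test_mrpf_window_boundaries_inclusive(self):
        t = make_transcript()
        wc = count_windows([t.main_aug - 3, t.main_aug + 6], t)
        assert wc.mRPF == 2

    def test_short_utr_urpf_is_zero(self):
        t = make_transcript(utr5=3, cds=60)
        assert count_windows([0, 1, 2], t).uRPF == 0

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            utr5 = int(rng.integers(0, 60))
            cds = 3 * int(rng.integers(4, 80))
            t = make_transcript(utr5, cds)
            p_sites = rng.integers(0, len(t), size=rng.integers(0, 30)).tolist()
            assert tuple(count_windows(p_sites, t)) == brute_force_windows(p_sites, t)

    def test_cds_partition(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            t = make_transcript(int(rng.integers(10, 50)), 3 * int(rng.integers(10, 60)))
            p = rng.integers(0, len(t), size=50).tolist()
            wc = count_windows(p, t)
            m = t.main_aug
            in_cds_head = sum(m <= x <= m + 6 for x in p)
            gap = sum(x in (m + 7, m + 8) for x in p)
            assert in_cds_head + gap + wc.iRPF == wc.cdsRPF


def _fps(tid, p_sites, sample, length=28):
    return [
        AlignedFootprint(tid, p - 12, length, sample, p_site=p) for p in p_sites
    ]


class TestSizeFactors:
    @pytest.fixture
    def spike(self):
        rng = np.random.default_rng(9)
        from recseq.synthetic_data import make_spike_ins

        return make_spike_ins(rng)[0]

    def test_geometric_mean_of_two_sites(self, spike):
        sites = [spike.main_aug] + spike.internal_augs
        fps = _fps(spike.transcript_id, [sites[0]] * 4 + [sites[1]] * 9, "s1")
        sf = spike_in_size_factors({"s1": fps}, [spike])
        assert sf.geometric_means["s1"] == pytest.approx(6.0)

    def test_max_referenced_factors(self, spike):
        sites = [spike.main_aug, spike.internal_augs[0]]
        fps_a = _fps(spike.transcript_id, [sites[0]] * 10 + [sites[1]] * 10, "a")
        fps_b = _fps(spike.transcript_id, [sites[0]] * 5 + [sites[1]] * 5, "b")
        sf = spike_in_size_factors({"a": fps_a, "b": fps_b}, [spike])
        assert sf.factors["a"] == pytest.approx(1.0)
        assert sf.factors["b"] == pytest.approx(2.0)
        assert (sf.factors >= 1).all()

    def test_identical_samples_all_unit(self, spike):
        fps = _fps(spike.transcript_id, [spike.main_aug] * 7, "a")
        fps2 = _fps(spike.transcript_id, [spike.main_aug] * 7, "b")
        sf = spike_in_size_factors({"a": fps, "b": fps2}, [spike])
        assert (sf.factors == 1.0).all()

    def test_sample_without_spike_reads_is_an_error(self, spike):
        fps = _fps(spike.transcript_id, [spike.main_aug] * 3, "a")
        with pytest.raises(ValueError, match="normalization impossible"):
            spike_in_size_factors({"a": fps, "b": []}, [spike])

    def test_recovers_planted_library_scales(self, small_study):
        config, paths, truth = small_study
        from recseq.annotation_io import read_transcriptome
        from recseq.read_processing import SampleSheet, process_fastq

        transcripts = read_transcriptome(paths["fasta"], paths["annotation"])
        sheet = SampleSheet(truth.samples["barcode"].to_dict())
        footprints, _ = process_fastq(paths["footprints"], sheet, transcripts)
        spikes = [t for t in transcripts if t.is_spike_in]
        sf = spike_in_size_factors(footprints, spikes)
        est = 1.0 / sf.factors  # relative library depth, max-referenced
        planted = truth.samples["library_scale"]
        ratio = (est / est.max()) / (planted / planted.max())
        # ~150 reads/site over 26 sites in this fixture: per-sample geometric
        # mean SE ~3%, compounded by max-referencing across six samples
        assert np.allclose(ratio, 1.0, atol=0.12)


class TestDensityAndRe:
    def test_density_units(self):
        t = make_transcript(utr5=50, cds=600)
        positions = list(np.linspace(t.main_aug, t.stop_last, 1380).astype(int))
        n, density = mrna_density(positions, t)
        assert n == 1380
        assert density == pytest.approx(2.3)

    def test_zero_reads_zero_density(self):
        assert mrna_density([], make_transcript())[1] == 0.0

    def test_density_linear_in_reads(self):
        t = make_transcript()
        pos = [t.main_aug + 5] * 10
        assert mrna_density(pos * 2, t)[1] == 2 * mrna_density(pos, t)[1]

    def test_re_arithmetic(self):
        assert recruitment_efficiency(50, 0.5) == pytest.approx(100.0)
        assert recruitment_efficiency(0, 0.5) == 0.0
        assert np.isnan(recruitment_efficiency(10, 0.0))


class TestMetagene:
    def test_shape_fixed(self):
        assert metagene([], []).shape == (10, 151)

    def test_single_read_single_cell(self):
        t = make_transcript(utr5=100, cds=300)
        fp = AlignedFootprint("t", t.main_aug - 12, 28, "s", p_site=t.main_aug)
        mg = metagene([fp], [t])
        assert mg.loc[28, -12] == 1
        assert mg.to_numpy().sum() == 1

    def test_rro_extremes(self):
        t = make_transcript(utr5=100, cds=300)
        all_maug = count_windows([t.main_aug] * 5, t)
        assert all_maug.iRPF / all_maug.cdsRPF == 0.0
        downstream = count_windows([t.main_aug + 20] * 5, t)
        assert downstream.iRPF / downstream.cdsRPF == 1.0


class TestRatioSummaries:
    @pytest.fixture
    def table(self):
        rows = []
        data = {
            ("t1", "s1"): dict(mRPF=100, iRPF=25, uRPF=2, cdsRPF=100),
            ("t2", "s1"): dict(mRPF=50, iRPF=10, uRPF=30, cdsRPF=80),
            ("t3", "s1"): dict(mRPF=10, iRPF=5, uRPF=1, cdsRPF=20),
        }
        for (tid, s), d in data.items():
            rows.append({"transcript_id": tid, "sample": s, **d})
        return pd.DataFrame(rows).set_index(["transcript_id", "sample"])

    def test_single_transcript_ratio(self, table):
        sub = table.loc[[("t1", "s1")]]
        out = ratio_summaries(sub)
        assert out.loc["s1", "irpf_cdsrpf_ratio"] == pytest.approx(0.25)

    def test_brute_force_sums(self, table):
        out = ratio_summaries(table)
        assert out.loc["s1", "irpf_cdsrpf_ratio"] == pytest.approx(40 / 200)
        assert out.loc["s1", "urpf_mrpf_ratio"] == pytest.approx(33 / 160)

    def test_exclusion_removes_from_both_sides(self, table):
        out = ratio_summaries(table, urpf_exclusions={"t2"})
        assert out.loc["s1", "urpf_mrpf_ratio"] == pytest.approx(3 / 110)
        # iRPF ratio unaffected by the uRPF exclusion list
        assert out.loc["s1", "irpf_cdsrpf_ratio"] == pytest.approx(40 / 200)


class TestNormalizationInvariance:
    def test_re_invariant_under_library_scaling(self):
        rng = np.random.default_rng(4)
        t = random_transcript(rng, "T", 60, 300)
        from recseq.synthetic_data import make_spike_ins

        spike = make_spike_ins(rng)[0]
        base_fps = _fps("T", [t.main_aug] * 20, "a") + _fps(
            spike.transcript_id, [spike.main_aug] * 10, "a"
        )
        scaled_fps = _fps("T", [t.main_aug] * 40, "b") + _fps(
            spike.transcript_id, [spike.main_aug] * 20, "b"
        )
        fps = {"a": base_fps, "b": scaled_fps}
        sf = spike_in_size_factors(fps, [spike])
        rna_reads = [AlignedFootprint("T", t.main_aug + 1, 60, s) for s in "ab"]
        table = build_count_table(
            fps, [t, spike], sf, {"a": rna_reads[:1], "b": rna_reads[1:]}
        )
        re_a = table.loc[("T", "a"), "RE"]
        re_b = table.loc[("T", "b"), "RE"]
        # doubling all counts and spike-ins together cancels exactly
        assert re_a == pytest.approx(re_b)
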