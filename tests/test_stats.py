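"""Mismatch-class rates, binomial site calling, comparisons, targeted loci."""
import numpy as np
import pandas as pd
import pytest

from rnaedit import (
    FilterParams,
    ReadSimConfig,
    build_pileup,
    build_scenario,
    call_sites,
    compare_conditions,
    filter_alignments,
    generate_reference,
    simulate_reads,
    site_stats_table,
    targeted_report,
    transcriptome_rates,
)
from rnaedit.simulate import adenosine_offsets
from rnaedit.stats import SampleResult, estimate_background
from rnaedit.pileup import PileupMatrix
from rnaedit.models import EditSite

from _oracles import binom_upper_tail
from conftest import make_dataset


def _site_row(base, tx_counts, gene="g", pos=0, biotype="mRNA"):
    a, c, g, t = tx_counts
    ref = {"A": a, "C": c, "G": g, "T": t}[base]
    return {
        "gene_id": gene, "contig": "chr", "pos": pos, "transcript_offset": pos,
        "strand": "+", "biotype": biotype, "transcript_base": base,
        "tx_A": a, "tx_C": c, "tx_G": g, "tx_T": t, "tx_N": 0,
        "coverage": a + c + g + t, "n_ref": ref, "n_alt": g,
        "f": g / (ref + g) if base == "A" and ref + g else np.nan,
    }


def test_weighted_aggregation_arithmetic():
    # two A sites with (alt, pair) = (1,10) and (3,30): A>G rate = 4/40
    df = pd.DataFrame(
        [_site_row("A", (9, 0, 1, 0), pos=1), _site_row("A", (27, 0, 3, 0), pos=2)]
    )
    rates = transcriptome_rates(df, expressed_threshold=10)
    ag = rates.set_index("class").loc["A>G"]
    assert (ag.numerator, ag.denominator) == (4, 40)
    assert ag.rate == pytest.approx(0.1)


def test_rrna_positions_rejected():
    df = pd.DataFrame([_site_row("A", (9, 0, 1, 0), biotype="rRNA")])
    with pytest.raises(ValueError, match="rRNA"):
        transcriptome_rates(df)


def test_all_rates_zero_without_errors_or_edits(clean_dataset):
    genome, ann, _, _, result = clean_dataset
    kept, _ = filter_alignments(result.alignments, ann)
    df = site_stats_table(build_pileup(kept, genome), ann)
    rates = transcriptome_rates(df)
    assert (rates["rate"].dropna() == 0).all()


def test_null_ag_rate_matches_error_model():
    """With uniform errors at rate e, each substitution class sees e/3."""
    genome, ann, _, _, result = make_dataset(
        seed=17, error_rate=0.003, indel_read_fraction=0.0, decoy_gene=None,
        edit_specs=(), n_host_mrna=30, mean_depth=60.0,
    )
    kept, _ = filter_alignments(result.alignments, ann)
    df = site_stats_table(build_pileup(kept, genome), ann)
    rates = transcriptome_rates(df)
    ag = rates.set_index("class").loc["A>G"]
    expect = 0.003 / 3
    se = np.sqrt(expect * (1 - expect) / ag.denominator)
    assert abs(ag.rate - expect) <= 3 * se


def test_aggregation_identity_coverage_weighted_mean(dataset):
    genome, ann, _, _, result = dataset
    kept, _ = filter_alignments(result.alignments, ann)
    df = site_stats_table(build_pileup(kept, genome), ann)
    sub = df[(df.transcript_base == "A") & (df.coverage >= 10)]
    pair = sub.n_ref + sub.n_alt
    weighted = (sub.f * pair).sum() / pair.sum()
    ag = transcriptome_rates(df).set_index("class").loc["A>G", "rate"]
    assert ag == pytest.approx(weighted, rel=1e-12)


def test_call_sites_zero_alt_not_called():
    df = pd.DataFrame([_site_row("A", (100, 0, 0, 0))])
    calls = call_sites(df, background_rate=0.001)
    assert calls["p"].iloc[0] == pytest.approx(1.0)
    assert not calls["called_edited"].iloc[0]


def test_call_sites_exact_binomial_tail():
    df = pd.DataFrame([_site_row("A", (90, 0, 10, 0))])
    calls = call_sites(df, background_rate=0.001)
    assert calls["p"].iloc[0] == pytest.approx(
        binom_upper_tail(10, 100, 0.001), rel=1e-9
    )
    assert calls["called_edited"].iloc[0]


def test_positive_control_power_across_seeds():
    """A 40%-rate site at ~200x is essentially always detected."""
    spec, genes = build_scenario(
        seed=2, n_host_mrna=4, n_phage_mrna=0, spacer=60, n_rrna=1, rrna_weight=0.2
    )
    genome, ann = generate_reference(spec, genes)
    gene = ann.by_id["hgene1"]
    offs = adenosine_offsets(genome, gene)
    site = EditSite("hgene1", int(offs[len(offs) // 2]), 0.4, "pc")
    called = 0
    n_seeds = 30
    for seed in range(n_seeds):
        res = simulate_reads(
            genome, ann, [site],
            ReadSimConfig(seed=seed, mean_depth=200.0, error_rate=0.001),
        )
        kept, _ = filter_alignments(res.alignments, ann)
        df = site_stats_table(build_pileup(kept, genome), ann)
        calls = call_sites(df)
        gpos = gene.transcript_to_genomic(site.offset)
        hit = calls[(calls.gene_id == "hgene1") & (calls.pos == gpos)]
        called += int(len(hit) == 1 and bool(hit.called_edited.iloc[0]))
    assert called == n_seeds


def test_monotonicity_of_estimate_in_true_rate():
    spec, genes = build_scenario(
        seed=4, n_host_mrna=3, n_phage_mrna=0, spacer=60, n_rrna=1, rrna_weight=0.2
    )
    genome, ann = generate_reference(spec, genes)
    gene = ann.by_id["hgene0"]
    offs = adenosine_offsets(genome, gene)
    offset = int(offs[len(offs) // 2])
    medians = []
    for rate in (0.02, 0.1, 0.3, 0.8):
        fs = []
        for seed in range(8):
            res = simulate_reads(
                genome, ann, [EditSite("hgene0", offset, rate)],
                ReadSimConfig(seed=seed, mean_depth=80.0, error_rate=0.0),
            )
            kept, _ = filter_alignments(res.alignments, ann)
            df = site_stats_table(build_pileup(kept, genome), ann)
            gpos = gene.transcript_to_genomic(offset)
            fs.append(float(df[(df.gene_id == "hgene0") & (df.pos == gpos)].f.iloc[0]))
        medians.append(np.median(fs))
    assert all(b >= a for a, b in zip(medians, medians[1:]))


def _sample_from(df, rates, sid, cond, tp):
    return SampleResult(sid, cond, tp, df, rates)


def test_compare_identical_inputs_zero_deltas(dataset):
    genome, ann, _, _, result = dataset
    kept, _ = filter_alignments(result.alignments, ann)
    df = site_stats_table(build_pileup(kept, genome), ann)
    rates = transcriptome_rates(df)
    calls = call_sites(df)
    comp, summary = compare_conditions(
        [
            _sample_from(calls, rates, "c0", "control", 0),
            _sample_from(calls, rates, "r0", "radar", 0),
        ]
    )
    assert (comp["delta_f"].abs() < 1e-12).all()
    assert len(summary) == 2


def test_compare_injected_site_tops_delta_ranking():
    genome, ann, sites, _, treated = make_dataset(
        seed=51, edit_specs=(("hgene1", 0.3, "only-site"),), decoy_gene=None,
        indel_read_fraction=0.0,
    )
    _, _, _, _, control = make_dataset(
        seed=52, edit_specs=(), decoy_gene=None, indel_read_fraction=0.0,
    )
    samples = []
    for sid, cond, res in (("ctrl", "control", control), ("rad", "radar", treated)):
        kept, _ = filter_alignments(res.alignments, ann)
        df = site_stats_table(build_pileup(kept, genome), ann)
        samples.append(
            _sample_from(call_sites(df), transcriptome_rates(df), sid, cond, 60)
        )
    comp, summary = compare_conditions(samples)
    top = comp.sort_values("delta_f", ascending=False).iloc[0]
    gene = ann.by_id["hgene1"]
    assert top.gene_id == "hgene1"
    assert top.pos == gene.transcript_to_genomic(sites[0].offset)
    tr = summary[summary.condition == "radar"].iloc[0]
    assert tr.fraction_unedited > 0.99


def test_compare_mismatched_references_rejected(dataset):
    genome, ann, _, _, result = dataset
    kept, _ = filter_alignments(result.alignments, ann)
    df = site_stats_table(build_pileup(kept, genome), ann)
    rates = transcriptome_rates(df)
    calls = call_sites(df)
    other = calls.copy()
    other["contig"] = other["contig"].map({"host": "elsewhere", "phage": "phage"})
    with pytest.raises(ValueError, match="reference"):
        compare_conditions(
            [
                _sample_from(calls, rates, "a", "control", 0),
                _sample_from(other, rates, "b", "radar", 0),
            ]
        )


def test_targeted_report_recovers_weak_site_and_flags():
    genome, ann, sites, _, result = make_dataset(
        seed=61, mean_depth=1000.0, decoy_gene=None, indel_read_fraction=0.0,
        n_host_mrna=3, n_phage_mrna=0, edit_specs=(("hgene1", 0.04, "ssrA-like"),),
    )
    kept, _ = filter_alignments(result.alignments, ann)
    pm = build_pileup(kept, genome)
    gene = ann.by_id["hgene1"]
    gpos = gene.transcript_to_genomic(sites[0].offset)
    loci = pd.DataFrame(
        [
            {"contig": "host", "pos": gpos + 1, "strand": gene.strand, "label": "ssrA-like"},
            {"contig": "host", "pos": 5, "strand": "+", "label": "uncovered"},
            {"contig": "nowhere", "pos": 10, "strand": "+", "label": "bad"},
        ]
    )
    report = targeted_report({"s1": pm}, loci)
    by_label = report.set_index("label")
    site_row = by_label.loc["ssrA-like"]
    from scipy import stats as sps

    n = site_row.n_ref + site_row.n_alt
    lo, hi = sps.binom.ppf([0.005, 0.995], int(n), 0.04)
    assert lo <= site_row.n_alt <= hi
    assert site_row.status == "ok"
    assert by_label.loc["uncovered"].status == "low_coverage"
    assert np.isnan(by_label.loc["uncovered"].f)
    assert by_label.loc["bad"].status == "outside_reference"


def test_targeted_report_minus_strand_pair():
    genome = {"chr": "A" * 1000 + "T" + "A" * 999}
    pm = PileupMatrix(genome)
    pm.counts["chr"][1000] = np.array([0, 4, 0, 96, 0])  # 96 T, 4 C
    loci = pd.DataFrame(
        [{"contig": "chr", "pos": 1001, "strand": "-", "label": "m"}]
    )
    report = targeted_report({"s": pm}, loci)
    assert report.f.iloc[0] == pytest.approx(0.04)


def test_background_estimate_is_median_of_other_classes(dataset):
    genome, ann, _, _, result = dataset
    kept, _ = filter_alignments(result.alignments, ann)
    df = site_stats_table(build_pileup(kept, genome), ann)
    rates = transcriptome_rates(df)
    bg = estimate_background(rates)
    manual = rates[rates["class"] != "A>G"]["rate"].median()
    assert bg == pytest.approx(manual)
    # an A>G signal from injected sites must not contaminate the background
    assert bg < 0.002
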