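"""Transcriptome-wide mismatch rates, editing-site calls, and comparisons.

The headline quantity is the rate of each of the 12 transcript-space
substitution classes X->Y over all expressed positions of non-rRNA genes:
rate(X->Y) = sum(n_Y) / sum(n_X + n_Y) over positions whose transcript base
is X with coverage at or above the expressed threshold. For A->G this is the
coverage-weighted mean editing fraction. On top of the raw rates sits an
explicit calling rule (the underlying experimental readout reports raw
frequencies only): an exact binomial upper-tail test of each site's
alternate count against a background substitution rate, Benjamini-Hochberg
corrected across tested sites.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pileup import PileupMatrix

TX_BASES = "ACGT"
CLASSES = [(x, y) for x in TX_BASES for y in TX_BASES if x != y]
_TX_COL = {b: f"tx_{b}" for b in TX_BASES}


def transcriptome_rates(
    site_df: pd.DataFrame,
    expressed_threshold: int = 10,
    sample: str = "",
    timepoint: int | None = None,
) -> pd.DataFrame:
    """Aggregate substitution rates per mismatch class over expressed positions.

    Only positions of non-rRNA genes with coverage >= ``expressed_threshold``
    qualify. Classes with zero qualifying denominator get rate NaN (reported
    missing downstream).
    """
    if (site_df["biotype"] == "rRNA").any():
        raise ValueError("site table contains rRNA positions; filter upstream")
    sub = site_df[site_df["coverage"] >= expressed_threshold]
    rows = []
    for x, y in CLASSES:
        at_x = sub[sub["transcript_base"] == x]
        num = int(at_x[_TX_COL[y]].sum())
        den = int((at_x[_TX_COL[x]] + at_x[_TX_COL[y]]).sum())
        rows.append(
            {
                "class": f"{x}>{y}",
                "from_base": x,
                "to_base": y,
                "numerator": num,
                "denominator": den,
                "rate": num / den if den else np.nan,
                "n_positions": len(at_x),
                "sample": sample,
                "timepoint": timepoint,
            }
        )
    out = pd.DataFrame(rows)
    if out["denominator"].eq(0).all():
        import warnings

        warnings.warn("no expressed positions; all mismatch rates undefined")
    return out


def estimate_background(rates: pd.DataFrame) -> float:
    """Background substitution rate: median of the 11 non-A>G class rates."""
    other = rates.loc[rates["class"] != "A>G", "rate"].dropna()
    if other.empty:
        raise ValueError("cannot estimate background: no non-A>G class has data")
    return float(other.median())


def call_sites(
    site_df: pd.DataFrame,
    background_rate: float | None = None,
    q_threshold: float = 0.05,
    expressed_threshold: int = 10,
) -> pd.DataFrame:
    """Call edited sites among expressed transcript adenosines.

    Each site's alternate (transcript G) count is tested against an exact
    binomial upper tail at the background rate, over the ref+alt pair count;
    Benjamini-Hochberg adjustment runs across all tested sites. A site is
    called edited when q <= ``q_threshold`` and its editing fraction exceeds
    the background.
    """
    if background_rate is None:
        background_rate = estimate_background(
            transcriptome_rates(site_df, expressed_threshold)
        )
    tested = site_df[
        (site_df["transcript_base"] == "A")
        & (site_df["coverage"] >= expressed_threshold)
        & (site_df["n_ref"] + site_df["n_alt"] > 0)
    ].copy()
    if tested.empty:
        tested["background"] = []
        tested["p"] = []
        tested["q"] = []
        tested["called_edited"] = []
        return tested
    n = (tested["n_ref"] + tested["n_alt"]).to_numpy().astype(np.int64)
    k = tested["n_alt"].to_numpy().astype(np.int64)  # signed: k-1 must not wrap
    tested["background"] = background_rate
    tested["p"] = sps.binom.sf(k - 1, n, background_rate)
    tested["q"] = multipletests(tested["p"].to_numpy(), method="fdr_bh")[1]
    tested["called_edited"] = (tested["q"] <= q_threshold) & (
        tested["f"] > background_rate
    )
    return tested


@dataclass
class SampleResult:
    """Per-sample analysis products entering the condition comparison."""

    sample_id: str
    condition: str  # 'control' or 'radar'
    timepoint: int  # minutes from onset of infection; 0 = uninfected
    sites: pd.DataFrame  # call_sites output
    rates: pd.DataFrame  # transcriptome_rates output


def compare_conditions(
    samples: list[SampleResult],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare editing between control and treatment across timepoints.

    Returns (comparison, summary). ``comparison`` holds per-site editing
    fractions for control vs treatment at each shared timepoint with their
    difference; ``summary`` holds, per sample, the A>G rate and the fraction
    of expressed adenosine positions not called edited (the headline
    'fraction unedited' statistic).
    """
    contigs = [set(s.sites["contig"].unique()) for s in samples if len(s.sites)]
    if contigs and any(c != contigs[0] for c in contigs):
        raise ValueError("samples do not share a reference (contig sets differ)")

    summary_rows = []
    for s in samples:
        n_tested = len(s.sites)
        n_called = int(s.sites["called_edited"].sum()) if n_tested else 0
        ag = s.rates.loc[s.rates["class"] == "A>G", "rate"]
        summary_rows.append(
            {
                "sample": s.sample_id,
                "condition": s.condition,
                "timepoint": s.timepoint,
                "n_expressed_A": n_tested,
                "n_called_edited": n_called,
                "fraction_unedited": 1 - n_called / n_tested if n_tested else np.nan,
                "ag_rate": float(ag.iloc[0]) if len(ag) else np.nan,
            }
        )
    summary = pd.DataFrame(summary_rows)

    key = ["contig", "pos", "gene_id", "strand"]
    comp_frames = []
    controls = {s.timepoint: s for s in samples if s.condition == "control"}
    for s in samples:
        if s.condition == "control" or s.timepoint not in controls:
            continue
        ctrl = controls[s.timepoint]
        merged = pd.merge(
            ctrl.sites[key + ["f", "coverage"]],
            s.sites[key + ["f", "coverage", "called_edited"]],
            on=key,
            suffixes=("_control", "_treatment"),
            how="outer",
        )
        merged["timepoint"] = s.timepoint
        merged["sample_treatment"] = s.sample_id
        merged["delta_f"] = merged["f_treatment"].fillna(0) - merged[
            "f_control"
        ].fillna(0)
        merged["direction"] = np.sign(merged["delta_f"]).astype(int)
        comp_frames.append(merged)
    comparison = (
        pd.concat(comp_frames, ignore_index=True)
        if comp_frames
        else pd.DataFrame(
            columns=key
            + [
                "f_control", "coverage_control", "f_treatment",
                "coverage_treatment", "called_edited", "timepoint",
                "sample_treatment", "delta_f", "direction",
            ]
        )
    )
    return comparison, summary


def load_loci(path: str | Path) -> pd.DataFrame:
    """Read a targeted-locus list: TSV with contig, pos (1-based), strand, label."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"contig", "pos", "strand", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"loci list {path} lacks columns: {sorted(missing)}")
    return df


def targeted_report(
    pileups: dict[str, PileupMatrix],
    loci: pd.DataFrame,
    expressed_threshold: int = 10,
) -> pd.DataFrame:
    """Editing fraction at user-specified loci, per sample.

    Loci are given 1-based with a gene strand: the A->G pair is (A,G) counts
    for plus-strand loci and (T,C) for minus. Low-coverage loci are flagged,
    not dropped; loci outside the reference get a row-level error status.
    """
    rows = []
    for _, locus in loci.iterrows():
        pos0 = int(locus["pos"]) - 1
        for sample, pm in pileups.items():
            row = {
                "label": locus["label"],
                "contig": locus["contig"],
                "pos": int(locus["pos"]),
                "strand": locus["strand"],
                "sample": sample,
                "status": "ok",
                "coverage": np.nan,
                "n_ref": np.nan,
                "n_alt": np.nan,
                "f": np.nan,
            }
            mat = pm.counts.get(locus["contig"])
            if mat is None or not 0 <= pos0 < len(mat):
                row["status"] = "outside_reference"
                rows.append(row)
                continue
            counts = mat[pos0]
            if locus["strand"] == "+":
                n_ref, n_alt = int(counts[0]), int(counts[2])  # A, G
            else:
                n_ref, n_alt = int(counts[3]), int(counts[1])  # T, C
            cov = int(counts.sum())
            row.update(coverage=cov, n_ref=n_ref, n_alt=n_alt)
            if cov < expressed_threshold:
                row["status"] = "low_coverage"
            elif n_ref + n_alt > 0:
                row["f"] = n_alt / (n_ref + n_alt)
            rows.append(row)
    return pd.DataFrame(rows)
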