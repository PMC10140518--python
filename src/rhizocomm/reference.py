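"""Bundled reference summaries from a published paddy-soil survey.

A field survey of rice paddies on Mollisols (Northeast China) sampled
bulk soil (BS), rhizosphere (R1) and rhizoplane (R2) compartments at the
tillering, heading and mature stages, three replicates each.  The
published per-group alpha-diversity means and the per-compartment network
sizes are bundled here so that the narrative arithmetic built on them —
percent changes between compartments, average degree from node and edge
counts — can be recomputed and checked without the raw sequence data.
"""

from __future__ import annotations

import pandas as pd

from rhizocomm.diversity import percent_increase

#: per stage x compartment means of the four alpha indices (rarefied OTU
#: counts; Shannon in nats, Simpson as dominance)
ALPHA_SUMMARY = pd.DataFrame(
    [
        ("tillering", "bulk", 6.67, 0.0044, 3103.93, 3117.76),
        ("tillering", "rhizosphere", 6.96, 0.0030, 3424.43, 3424.77),
        ("tillering", "rhizoplane", 6.43, 0.0055, 3221.06, 3202.29),
        ("heading", "bulk", 7.11, 0.0024, 3531.04, 3537.76),
        ("heading", "rhizosphere", 7.18, 0.0017, 3708.30, 3681.90),
        ("heading", "rhizoplane", 6.40, 0.0063, 3165.68, 3150.80),
        ("mature", "bulk", 6.80, 0.0056, 3244.54, 3246.05),
        ("mature", "rhizosphere", 7.15, 0.0018, 3729.68, 3755.11),
        ("mature", "rhizoplane", 6.24, 0.0074, 3115.66, 3122.62),
    ],
    columns=["stage", "compartment", "shannon", "simpson", "ace", "chao1"],
)

#: per-compartment co-occurrence network sizes (prevalent OTUs, nodes with
#: >= 1 edge, thresholded Spearman edges)
NETWORK_SUMMARY = pd.DataFrame(
    [
        ("bulk", 2697, 982, 3633),
        ("rhizosphere", 3070, 749, 725),
        ("rhizoplane", 2295, 577, 729),
    ],
    columns=["compartment", "original_otus", "total_nodes", "total_edges"],
)


def alpha_mean(stage: str, compartment: str, index: str) -> float:
    row = ALPHA_SUMMARY[
        (ALPHA_SUMMARY["stage"] == stage)
        & (ALPHA_SUMMARY["compartment"] == compartment)
    ]
    if row.empty:
        raise KeyError(f"no summary row for ({stage}, {compartment})")
    return float(row.iloc[0][index])


def alpha_percent_increase(
    index: str, stage: str, compartment_a: str, compartment_b: str
) -> float:
    """Percent change of an alpha index between two compartments at one
    stage, from the bundled means (2-decimal convention)."""
    return percent_increase(
        alpha_mean(stage, compartment_a, index),
        alpha_mean(stage, compartment_b, index),
    )


def network_average_degree(compartment: str) -> float:
    """Average degree 2E/N implied by the bundled node and edge counts."""
    row = NETWORK_SUMMARY[NETWORK_SUMMARY["compartment"] == compartment]
    if row.empty:
        raise KeyError(f"no network summary for {compartment!r}")
    return 2.0 * float(row.iloc[0]["total_edges"]) / float(
        row.iloc[0]["total_nodes"]
    )
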