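"""Published study constants used as inputs and for arithmetic cross-checks.

These are the printed cohort composition (per-site, per-class image counts)
and the reported 10-run mean test performance of the original two-site
study.  The counts parameterize the default synthetic scenario; the
performance means support recomputing the reported absolute and relative
federated-over-single-node gains.  Nothing here is a result of this
package's own training runs.
"""

from __future__ import annotations

from .phenotypes import PathogenicClass

__all__ = [
    "SITE_CLASS_COUNTS",
    "HOLDOUT_COUNTS",
    "TOTAL_PATIENTS",
    "REPORTED_PERFORMANCE",
    "class_percentages",
    "reported_gains",
]

#: published image counts per site and pathogenic-mechanism class
SITE_CLASS_COUNTS: dict[str, dict[PathogenicClass, int]] = {
    "NIH": {
        PathogenicClass.control: 84,
        PathogenicClass.exon_skipping: 71,
        PathogenicClass.glycine_substitution: 94,
        PathogenicClass.pseudoexon_insertion: 51,
    },
    "UCL": {
        PathogenicClass.control: 7,
        PathogenicClass.exon_skipping: 11,
        PathogenicClass.glycine_substitution: 5,
        PathogenicClass.pseudoexon_insertion: 8,
    },
}

#: held-out test images per site (total 24)
HOLDOUT_COUNTS: dict[str, int] = {"NIH": 20, "UCL": 4}

TOTAL_PATIENTS = 90

#: reported mean (STD) test metrics over 10 runs, per arm
REPORTED_PERFORMANCE: dict[str, dict[str, float]] = {
    "single_node_NIH": {"f1_mean": 0.747, "f1_std": 0.024,
                        "accuracy_mean": 0.754, "accuracy_std": 0.022},
    "single_node_UCL": {"f1_mean": 0.582, "f1_std": 0.037,
                        "accuracy_mean": 0.567, "accuracy_std": 0.038},
    "federated": {"f1_mean": 0.820, "f1_std": 0.032,
                  "accuracy_mean": 0.825, "accuracy_std": 0.031},
}


def class_percentages(counts: dict[PathogenicClass, int]) -> dict[PathogenicClass, float]:
    """Per-class share of a site's images, in percent (one decimal)."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty class counts")
    return {c: round(100.0 * n / total, 1) for c, n in counts.items()}


def reported_gains() -> dict[str, float]:
    """Absolute and relative federated-over-single-node gains recomputed
    from the reported arm means (percent values rounded to one decimal)."""
    fed = REPORTED_PERFORMANCE["federated"]
    out: dict[str, float] = {}
    for site in ("NIH", "UCL"):
        single = REPORTED_PERFORMANCE[f"single_node_{site}"]
        for metric in ("f1", "accuracy"):
            abs_gain = fed[f"{metric}_mean"] - single[f"{metric}_mean"]
            out[f"{metric}_gain_vs_{site}"] = round(abs_gain, 3)
            out[f"{metric}_gain_vs_{site}_pct"] = round(
                100.0 * abs_gain / single[f"{metric}_mean"], 1
            )
    return out
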