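"""Array-level differential methylation and expression fold-change filters.

Knockout-vs-control comparisons without replicates reduce to simple effect
filters: probes are first cleaned of sex chromosomes and SNP overlaps, then
thresholded on the beta-value difference (|Δβ| > 0.2 by default, strict
inequalities); expression uses |log2 fold change| > 2 on pseudocounted
reads-per-million. The module consumes already-normalised betas — array
preprocessing is upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ProbeAnnotation",
    "DMResult",
    "DEResult",
    "filter_probes",
    "differential_cpgs",
    "differential_genes",
]

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass(frozen=True)
class ProbeAnnotation:
    probe_id: str
    chromosome: str
    snp_overlap: bool


@dataclass(frozen=True)
class DMResult:
    threshold: float
    n_hyper: int
    n_hypo: int
    hyper_ids: tuple[str, ...]
    hypo_ids: tuple[str, ...]


@dataclass(frozen=True)
class DEResult:
    log2fc_threshold: float
    n_up: int
    n_down: int
    table: pd.DataFrame  # gene, rpm_ko, rpm_wt, log2fc


def filter_probes(
    betas_ko: Mapping[str, float],
    betas_wt: Mapping[str, float],
    annotation: Iterable[ProbeAnnotation],
) -> set[str]:
    """Probes measured in both samples, autosomal, and free of SNP overlap."""
    annot = {a.probe_id: a for a in annotation}
    if not annot:
        raise ValueError("empty probe annotation")
    shared = set(betas_ko) & set(betas_wt)
    missing = sorted(shared - set(annot))
    if missing:
        raise ValueError(f"probes missing annotation: {missing[:10]}")
    return {
        p
        for p in shared
        if annot[p].chromosome not in SEX_CHROMOSOMES and not annot[p].snp_overlap
    }


def differential_cpgs(
    betas_ko: Mapping[str, float],
    betas_wt: Mapping[str, float],
    retained: Iterable[str],
    threshold: float = 0.2,
) -> DMResult:
    """Threshold the beta difference ko − wt over retained probes.

    Strictly greater than ``threshold`` counts as hypermethylated, strictly
    below ``−threshold`` as hypomethylated; boundary-equal probes fall in
    neither set.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    hyper, hypo = [], []
    for probe in retained:
        ko, wt = float(betas_ko[probe]), float(betas_wt[probe])
        for name, b in (("ko", ko), ("wt", wt)):
            if not 0.0 <= b <= 1.0:
                raise ValueError(f"beta_{name} for {probe!r} outside [0, 1]: {b}")
        d = ko - wt
        if d > threshold:
            hyper.append(probe)
        elif d < -threshold:
            hypo.append(probe)
    hyper.sort()
    hypo.sort()
    return DMResult(
        threshold=threshold,
        n_hyper=len(hyper),
        n_hypo=len(hypo),
        hyper_ids=tuple(hyper),
        hypo_ids=tuple(hypo),
    )


def differential_genes(
    rpm_ko: Mapping[str, float],
    rpm_wt: Mapping[str, float],
    log2fc_threshold: float = 2.0,
    pseudocount: float = 0.1,
) -> DEResult:
    """log2 fold change on pseudocounted RPM, strict threshold both ways.

    The pseudocount (default 0.1 RPM) keeps zero-expression genes finite; it
    is the main lever when reconciling counts against tables derived from
    other zero-handling conventions.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    genes = sorted(set(rpm_ko) & set(rpm_wt))
    rows = []
    for g in genes:
        ko, wt = float(rpm_ko[g]), float(rpm_wt[g])
        if ko < 0 or wt < 0:
            raise ValueError(f"negative RPM for gene {g!r}")
        log2fc = np.log2((ko + pseudocount) / (wt + pseudocount))
        rows.append((g, ko, wt, log2fc))
    table = pd.DataFrame(rows, columns=["gene", "rpm_ko", "rpm_wt", "log2fc"])
    n_up = int((table["log2fc"] > log2fc_threshold).sum())
    n_down = int((table["log2fc"] < -log2fc_threshold).sum())
    return DEResult(
        log2fc_threshold=log2fc_threshold, n_up=n_up, n_down=n_down, table=table
    )
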