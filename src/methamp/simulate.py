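"""Synthetic data generators for every pipeline input, with ground truth.

Three generators cover the three analysis arms:

* ``simulate_cohort`` — blood cohorts (healthy / aplastic anemia / dyskeratosis
  congenita) whose three clock-CpG betas follow the linear age model plus
  Gaussian noise and group-specific age-acceleration offsets, and whose
  telomere length declines linearly with age plus disease-specific attrition.
  Epigenetic and telomere offsets are drawn independently, so their deltas are
  uncorrelated by construction.
* ``simulate_amplicon_reads`` — bisulfite amplicon read populations drawn from
  a three-component epiallele mixture (fully unmethylated / stochastic
  per-CpG / fully methylated), converted in silico and sequenced with iid
  substitution errors.
* ``simulate_beta_matrix`` / ``simulate_expression_table`` — array beta and
  RNA-seq RPM matrices with planted differential probes/genes.

Every generator is deterministic given its seed and returns a machine-readable
truth table alongside the data, sufficient to score downstream operations
without re-deriving latent variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import Amplicon, Strand, bisulfite_convert, reverse_complement
from .array_dm import ProbeAnnotation
from .clock import BLOOD_CLOCK_3CPG, ClockModel, predict_epigenetic_age
from .cohort import CellFraction, Group, SubjectRecord

__all__ = [
    "CohortConfig",
    "MixtureConfig",
    "invert_clock",
    "simulate_cohort",
    "simulate_amplicon_reads",
    "simulate_beta_matrix",
    "simulate_expression_table",
]

# Group-level defaults: epigenetic age-acceleration offsets (years) and
# telomere-age offsets (years) for the emulated disease cohorts, and the
# per-group scatter of the epigenetic delta (years) sized so that healthy
# donors show MAE ~5.45 y (sd * sqrt(2/pi)) and patient cohorts the weaker
# age correlation seen in bone-marrow-failure blood.
DEFAULT_EPI_OFFSETS = {Group.HEALTHY: 0.0, Group.AA: 6.06, Group.DKC: 16.36}
DEFAULT_TELO_OFFSETS = {Group.HEALTHY: 0.0, Group.AA: 19.05, Group.DKC: 84.14}
DEFAULT_EPI_SCATTER = {Group.HEALTHY: 6.83, Group.AA: 11.6, Group.DKC: 12.0}
DEFAULT_N = {Group.HEALTHY: 243, Group.AA: 70, Group.DKC: 18}

PHRED_QUALITY = 37  # constant FASTQ quality unless an error model is enabled


@dataclass
class CohortConfig:
    """Conditions for one simulated blood cohort."""

    seed: int
    n_per_group: dict[Group, int] = field(default_factory=lambda: dict(DEFAULT_N))
    age_range: tuple[float, float] = (18.0, 80.0)
    clock: ClockModel = BLOOD_CLOCK_3CPG
    beta_noise_sd: float = 0.01
    epi_offsets: dict[Group, float] = field(
        default_factory=lambda: dict(DEFAULT_EPI_OFFSETS)
    )
    epi_scatter_sd: dict[Group, float] = field(
        default_factory=lambda: dict(DEFAULT_EPI_SCATTER)
    )
    telomere_slope: float = -0.06  # kb per year
    telomere_intercept: float = 9.5  # kb at age 0
    telomere_noise_sd: float = 0.5  # kb
    telo_offsets: dict[Group, float] = field(
        default_factory=lambda: dict(DEFAULT_TELO_OFFSETS)
    )
    cell_fraction: CellFraction = CellFraction.GRANULOCYTES

    def __post_init__(self) -> None:
        if self.beta_noise_sd < 0 or self.telomere_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if any(sd < 0 for sd in self.epi_scatter_sd.values()):
            raise ValueError("scatter sds must be non-negative")
        lo, hi = self.age_range
        if lo <= 0 or hi <= lo:
            raise ValueError("age range must be positive and increasing")


@dataclass
class MixtureConfig:
    """Three-component epiallele mixture for amplicon read simulation.

    ``weights`` are the probabilities of a molecule being fully unmethylated,
    stochastically methylated (iid Bernoulli(theta) per CpG) or fully
    methylated. Defaults emulate a healthy blood sample at a CpG-island-shore
    target: mostly unmethylated molecules with a large stochastic fraction.
    """

    seed: int
    weights: tuple[float, float, float] = (0.55, 0.40, 0.05)  # (w_U, w_S, w_M)
    theta: float = 0.3
    n_reads: int = 4000
    error_rate: float = 0.0
    read_length: int | None = None  # None: read spans the whole amplicon
    ot_fraction: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9 or min(self.weights) < 0:
            raise ValueError("mixture weights must lie on the simplex")
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must lie in [0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must lie in [0, 1)")
        if not 0.0 <= self.ot_fraction <= 1.0:
            raise ValueError("ot_fraction must lie in [0, 1]")


def invert_clock(
    target_age: float, model: ClockModel = BLOOD_CLOCK_3CPG
) -> tuple[dict[str, float], bool]:
    """Beta values whose clock prediction equals ``target_age`` exactly.

    The inversion is underdetermined (one age, several betas); the convention
    here anchors every beta at 0.5 and shifts each by
    ``sign(w_i) * (target - f(0.5)) / sum(|w|)``, i.e. every marker carries a
    deviation share proportional to |weight| in prediction space. Returns the
    betas (clipped to [0, 1]) and a saturation flag; when no beta clips, the
    round trip through the clock is exact.
    """
    weights = model.weights
    f_half = model.intercept + 0.5 * weights.sum()
    shift = (target_age - f_half) / np.abs(weights).sum()
    raw = 0.5 + np.sign(weights) * shift
    clipped = np.clip(raw, 0.0, 1.0)
    saturated = bool(np.any(raw != clipped))
    return dict(zip(model.marker_ids, clipped.tolist())), saturated


def simulate_cohort(config: CohortConfig) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate subjects plus a truth table of all latent offsets.

    Per subject: age ~ U(age_range); target epigenetic age = age + group
    offset + N(0, group scatter); betas from ``invert_clock`` plus
    N(0, beta_noise_sd) clipped to [0, 1]; telomere_kb = intercept +
    slope * (age + group telomere offset) + N(0, sd), floored at 0.1 kb.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    subjects: list[SubjectRecord] = []
    rows = []
    for group, n in config.n_per_group.items():
        group = Group(group)
        epi_off = config.epi_offsets.get(group, 0.0)
        scatter = config.epi_scatter_sd.get(group, 0.0)
        telo_off = config.telo_offsets.get(group, 0.0)
        for i in range(n):
            sid = f"{group.value}_{i:04d}"
            age = float(rng.uniform(lo, hi))
            target = age + epi_off + float(rng.normal(0.0, scatter))
            betas, saturated = invert_clock(target, config.clock)
            if config.beta_noise_sd > 0:
                noisy = {
                    m: float(np.clip(b + rng.normal(0.0, config.beta_noise_sd), 0, 1))
                    for m, b in betas.items()
                }
            else:
                noisy = betas
            telo_true = (
                config.telomere_intercept
                + config.telomere_slope * (age + telo_off)
            )
            telo_kb = max(telo_true + float(rng.normal(0.0, config.telomere_noise_sd)), 0.1)
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    chronological_age=age,
                    group=group,
                    betas=noisy,
                    telomere_kb=telo_kb,
                    cell_fraction=config.cell_fraction,
                )
            )
            rows.append(
                {
                    "subject_id": sid,
                    "group": group.value,
                    "age": age,
                    "epi_offset": epi_off,
                    "epi_target_age": target,
                    "epi_delta_target": target - age,
                    "clock_saturated": saturated,
                    "telo_offset": telo_off,
                    "telomere_true_kb": telo_true,
                    "telomere_kb": telo_kb,
                }
            )
    return subjects, pd.DataFrame(rows)


def simulate_amplicon_reads(
    amplicon: Amplicon, config: MixtureConfig
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Draw one FASTQ read per molecule from the epiallele mixture.

    Each molecule draws a class (U/S/M) by the mixture weights, a methylation
    pattern accordingly, and a bisulfite strand; the reference is converted in
    silico with the pattern's methylated CpGs protected, truncated to
    ``read_length`` from the read's 5' end, and hit with iid substitution
    errors. Qualities are constant Q37. Truth rows carry read id, class,
    pattern and strand.
    """
    if amplicon.n_cpgs == 0:
        raise ValueError("amplicon has no CpG sites")
    rng = np.random.default_rng(config.seed)
    w_u, w_s, w_m = config.weights
    n_cpgs = amplicon.n_cpgs
    records: list[SeqRecord] = []
    rows = []
    bases = np.array(list("ACGT"))
    for i in range(config.n_reads):
        cls = rng.choice(("U", "S", "M"), p=(w_u, w_s, w_m))
        if cls == "U":
            states = np.zeros(n_cpgs, dtype=bool)
        elif cls == "M":
            states = np.ones(n_cpgs, dtype=bool)
        else:
            states = rng.random(n_cpgs) < config.theta
        pattern = "".join("M" if s else "U" for s in states)
        meth_positions = {
            p for p, s in zip(amplicon.cpg_positions, states) if s
        }
        strand = Strand.OT if rng.random() < config.ot_fraction else Strand.OB
        seq = bisulfite_convert(amplicon.sequence, strand, meth_positions)
        if config.read_length is not None:
            seq = seq[: config.read_length]
        if config.error_rate > 0:
            chars = np.array(list(seq))
            hits = np.flatnonzero(rng.random(len(chars)) < config.error_rate)
            for j in hits:
                alternatives = bases[bases != chars[j]]
                chars[j] = alternatives[rng.integers(len(alternatives))]
            seq = "".join(chars)
        read_id = f"read_{i:06d}"
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [PHRED_QUALITY] * len(seq)
        records.append(rec)
        rows.append(
            {"read_id": read_id, "class": cls, "pattern": pattern, "strand": strand.value}
        )
    return records, pd.DataFrame(rows)


def simulate_beta_matrix(
    n_probes: int = 10_000,
    n_hyper: int = 150,
    n_hypo: int = 120,
    effect: float = 0.3,
    noise_sd: float = 0.02,
    x_y_fraction: float = 0.05,
    snp_fraction: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[ProbeAnnotation], pd.DataFrame]:
    """Array beta matrix with planted differential probes.

    Null probes: wt ~ U(0.05, 0.95), ko = wt + N(0, noise_sd) clipped to
    [0, 1]. Planted probes get exactly +/-``effect`` (wt drawn so the shifted
    beta stays inside [0, 1]). X/Y and SNP annotations land only on null
    probes, so planted probes always survive filtering. Returns the beta
    table, the annotation list and a truth table of planted probe ids.
    """
    rng = np.random.default_rng(seed)
    n_flagged = int(n_probes * (x_y_fraction + snp_fraction))
    if n_hyper + n_hypo + n_flagged > n_probes:
        raise ValueError("planted plus flagged probes exceed n_probes")
    probe_ids = [f"cg{i:07d}" for i in range(n_probes)]
    perm = rng.permutation(n_probes)
    hyper_idx = perm[:n_hyper]
    hypo_idx = perm[n_hyper : n_hyper + n_hypo]
    n_xy = int(n_probes * x_y_fraction)
    n_snp = int(n_probes * snp_fraction)
    xy_idx = set(perm[n_hyper + n_hypo : n_hyper + n_hypo + n_xy])
    snp_idx = set(
        perm[n_hyper + n_hypo + n_xy : n_hyper + n_hypo + n_xy + n_snp]
    )

    wt = rng.uniform(0.05, 0.95, size=n_probes)
    ko = np.clip(wt + rng.normal(0.0, noise_sd, size=n_probes), 0.0, 1.0)
    wt[hyper_idx] = rng.uniform(0.05, 0.95 - effect, size=n_hyper)
    ko[hyper_idx] = wt[hyper_idx] + effect
    wt[hypo_idx] = rng.uniform(0.05 + effect, 0.95, size=n_hypo)
    ko[hypo_idx] = wt[hypo_idx] - effect

    autosomes = [str(c) for c in range(1, 23)]
    annotation = []
    for i, pid in enumerate(probe_ids):
        if i in xy_idx:
            chrom = "X" if rng.random() < 0.5 else "Y"
        else:
            chrom = autosomes[int(rng.integers(22))]
        annotation.append(
            ProbeAnnotation(probe_id=pid, chromosome=chrom, snp_overlap=i in snp_idx)
        )

    betas = pd.DataFrame({"probe_id": probe_ids, "beta_ko": ko, "beta_wt": wt})
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "planted": ["hyper" if i in set(hyper_idx) else "hypo" if i in set(hypo_idx) else "null" for i in range(n_probes)],
        }
    )
    return betas, annotation, truth


def simulate_expression_table(
    n_genes: int = 10_000,
    n_up: int = 30,
    n_down: int = 25,
    fold: float = 8.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPM expression table with planted fold-changed genes.

    Null genes share an RPM value between conditions (lognormal, median ~10);
    planted genes multiply/divide the wt RPM by ``fold``, with wt floored at
    1 RPM so the pseudocount cannot mask the planted effect.
    """
    if n_up + n_down > n_genes:
        raise ValueError("planted genes exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"ENSG{i:08d}" for i in range(n_genes)]
    wt = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=n_genes)
    ko = wt.copy()
    perm = rng.permutation(n_genes)
    up_idx, down_idx = perm[:n_up], perm[n_up : n_up + n_down]
    wt[up_idx] = np.maximum(wt[up_idx], 1.0)
    wt[down_idx] = np.maximum(wt[down_idx], 1.0)
    ko[up_idx] = wt[up_idx] * fold
    ko[down_idx] = wt[down_idx] / fold
    table = pd.DataFrame({"gene": genes, "rpm_ko": ko, "rpm_wt": wt})
    status = np.array(["null"] * n_genes, dtype=object)
    status[up_idx] = "up"
    status[down_idx] = "down"
    truth = pd.DataFrame({"gene": genes, "planted": status})
    return table, truth
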