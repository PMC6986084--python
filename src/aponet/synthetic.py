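"""Synthetic expression data with known ground truth.

Emulates the bahiagrass study design — three phenotypic classes (sexual
diploid with 2 genotypes, apomictic tetraploid with 3, sexual tetraploid
with 1), three clone replicates per genotype, leaf tissue — so that every
downstream stage (specificity, two-step DE, network, candidate filtering,
enrichment) can be tested against planted labels without any sequencing data.

Count model
-----------
Counts are negative binomial with mean/dispersion parameterization
(``var = mu + dispersion * mu**2``).  Each transcript has a log-uniform
baseline mean; each (transcript, genotype) pair receives a multiplicative
log-normal effect shared by the genotype's clones, so genotypes of a class
differ in expression the way real accessions do and the within-class
equal-expression filter has actual work to do.  Planted structure:

* class-specific transcripts — zero mean outside their class;
* DE transcripts — mean shifted by ``2**(+-de_log2fc)`` in one target class;
* coexpression modules — transcripts rewritten to share a latent per-sample
  profile plus log-normal noise (:func:`plant_modules`);
* ACR transcripts — a subset of ids later given alignment hits inside the
  marker-delimited intervals (:func:`generate_annotation_and_hits`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import METADATA_COLUMNS, ExpressionMatrix
from .synteny import IntervalSet

DEFAULT_CLASSES = (("2X_sex", 2), ("4X_apo", 3), ("4X_sex", 1))


@dataclass
class StudyDesign:
    """Phenotypic classes, genotypes per class, clones and tissues."""

    classes: tuple = DEFAULT_CLASSES
    clones_per_genotype: int = 3
    tissues: tuple = ("leaf",)

    def __post_init__(self):
        if self.clones_per_genotype < 1:
            raise ValueError("clones_per_genotype must be >= 1")
        for label, n in self.classes:
            if n < 1:
                raise ValueError(f"class {label!r} must have >= 1 genotype")

    @property
    def class_labels(self) -> list[str]:
        return [label for label, _ in self.classes]

    def metadata(self) -> pd.DataFrame:
        rows = []
        g_idx = 0
        for label, n_geno in self.classes:
            for _ in range(n_geno):
                g_idx += 1
                genotype = f"G{g_idx:02d}_{label}"
                for clone in range(1, self.clones_per_genotype + 1):
                    for tissue in self.tissues:
                        sample = f"{genotype}_c{clone}"
                        if len(self.tissues) > 1:
                            sample = f"{sample}_{tissue}"
                        rows.append((sample, genotype, f"c{clone}", tissue, label))
        return pd.DataFrame(rows, columns=list(METADATA_COLUMNS))


@dataclass
class SimulationParams:
    """Knobs of the generator; defaults are the package's reference conditions."""

    n_transcripts: int = 2000
    baseline_mean_log_range: tuple[float, float] = (math.log(5.0), math.log(500.0))
    nb_dispersion: float = 0.05
    genotype_sd: float = 0.1
    frac_specific_per_class: dict = field(
        default_factory=lambda: {"4X_apo": 0.10, "2X_sex": 0.02, "4X_sex": 0.005})
    frac_de: float = 0.05
    de_log2fc: float = 2.0
    n_modules: int = 5
    module_size: int = 30
    module_noise_sd: float = 0.25
    module_amplitude: float = 1.0
    n_acr: int = 80
    seed: int = 0

    def __post_init__(self):
        fracs = list(self.frac_specific_per_class.values()) + [self.frac_de]
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("specific + DE fractions must jointly be <= 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.genotype_sd < 0:
            raise ValueError("genotype_sd must be >= 0")
        if self.de_log2fc < 0:
            raise ValueError("de_log2fc must be >= 0")
        if self.n_modules * self.module_size > self.n_transcripts:
            raise ValueError("n_modules * module_size exceeds n_transcripts")


@dataclass
class GroundTruth:
    """Planted labels emitted by the generator, for recovery tests."""

    transcript_ids: list = field(default_factory=list)
    specific_sets: dict = field(default_factory=dict)       # class -> set of ids
    de_sets: dict = field(default_factory=dict)             # (clsA, clsB) -> (up_in_A, up_in_B)
    module_assignment: dict = field(default_factory=dict)   # id -> module index
    acr_set: set = field(default_factory=set)
    go_map: dict = field(default_factory=dict)              # id -> set of term ids

    def de_union(self) -> set:
        out: set = set()
        for up, down in self.de_sets.values():
            out |= set(up) | set(down)
        return out

    def consistent_de(self, focus_class: str) -> set:
        """Transcripts planted as DE in every comparison involving ``focus_class``."""
        sets = [set(up) | set(down) for (a, b), (up, down) in self.de_sets.items()
                if focus_class in (a, b)]
        if not sets:
            return set()
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out

    def to_json(self, path) -> None:
        payload = {
            "transcript_ids": list(self.transcript_ids),
            "specific_sets": {k: sorted(v) for k, v in self.specific_sets.items()},
            "de_sets": {f"{a}|{b}": [sorted(up), sorted(dn)]
                        for (a, b), (up, dn) in self.de_sets.items()},
            "module_assignment": {k: int(v) for k, v in self.module_assignment.items()},
            "acr_set": sorted(self.acr_set),
            "go_map": {k: sorted(v) for k, v in self.go_map.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            transcript_ids=payload["transcript_ids"],
            specific_sets={k: set(v) for k, v in payload["specific_sets"].items()},
            de_sets={tuple(k.split("|")): (set(up), set(dn))
                     for k, (up, dn) in payload["de_sets"].items()},
            module_assignment={k: int(v) for k, v in payload["module_assignment"].items()},
            acr_set=set(payload["acr_set"]),
            go_map={k: set(v) for k, v in payload["go_map"].items()},
        )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with var = mu + dispersion * mu**2; zero mean -> zero count."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        size = 1.0 / dispersion
        p = size / (size + mean[pos])
        out[pos] = rng.negative_binomial(size, p)
    return out


def generate_counts(
    design: StudyDesign, params: SimulationParams
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a seeded count matrix with planted specific / DE / ACR labels."""
    rng = np.random.default_rng(params.seed)
    meta = design.metadata()
    n = params.n_transcripts
    ids = [f"T{i:06d}" for i in range(1, n + 1)]
    truth = GroundTruth(transcript_ids=list(ids))

    lo, hi = params.baseline_mean_log_range
    base_log_mean = rng.uniform(lo, hi, size=n)

    # planted labels: specific sets first, DE from the remainder (disjoint)
    pool = rng.permutation(n)
    cursor = 0
    specific_class = np.full(n, "", dtype=object)
    for label in design.class_labels:
        frac = params.frac_specific_per_class.get(label, 0.0)
        k = int(frac * n)  # floor rule
        chosen = pool[cursor:cursor + k]
        cursor += k
        specific_class[chosen] = label
        truth.specific_sets[label] = {ids[i] for i in chosen}
    n_de = int(params.frac_de * n)
    de_idx = pool[cursor:cursor + n_de]
    cursor += n_de

    # each DE transcript targets one class (cycled) with a random direction
    labels = design.class_labels
    de_target = np.full(n, "", dtype=object)
    de_sign = np.zeros(n)
    for j, i in enumerate(de_idx):
        de_target[i] = labels[j % len(labels)]
        de_sign[i] = 1.0 if rng.random() < 0.5 else -1.0
    for a_i in range(len(labels)):
        for b_i in range(a_i + 1, len(labels)):
            a, b = labels[a_i], labels[b_i]
            up_a, up_b = set(), set()
            for i in de_idx:
                if de_target[i] == a:
                    (up_a if de_sign[i] > 0 else up_b).add(ids[i])
                elif de_target[i] == b:
                    (up_b if de_sign[i] > 0 else up_a).add(ids[i])
            truth.de_sets[(a, b)] = (up_a, up_b)

    # ACR ids: half drawn from the planted specific/DE pool, half from the rest,
    # so the candidate intersection downstream is non-trivial in both directions
    labelled = sorted(set().union(*truth.specific_sets.values()) | truth.de_union())
    unlabelled = sorted(set(ids) - set(labelled))
    k_lab = min(params.n_acr // 2, len(labelled))
    k_unl = min(params.n_acr - k_lab, len(unlabelled))
    acr = list(rng.choice(labelled, size=k_lab, replace=False)) if k_lab else []
    acr += list(rng.choice(unlabelled, size=k_unl, replace=False)) if k_unl else []
    truth.acr_set = set(acr)

    # per-(transcript, genotype) log-normal effect shared by the clones
    genotypes = meta["genotype"].unique()
    geno_class = meta.drop_duplicates("genotype").set_index("genotype")["phenotypic_class"]
    geno_effect = rng.normal(0.0, params.genotype_sd, size=(n, len(genotypes)))

    mean = np.empty((n, len(meta)), dtype=float)
    geno_col = {g: j for j, g in enumerate(genotypes)}
    log2 = math.log(2.0)
    for s_j, row in enumerate(meta.itertuples(index=False)):
        g_j = geno_col[row.genotype]
        cls = row.phenotypic_class
        mu = np.exp(base_log_mean + geno_effect[:, g_j])
        mu[(specific_class != "") & (specific_class != cls)] = 0.0
        shift = (de_target == cls)
        mu[shift] *= np.exp(de_sign[shift] * params.de_log2fc * log2)
        mean[:, s_j] = mu

    counts = _nb_draw(rng, mean, params.nb_dispersion)
    matrix = ExpressionMatrix(
        pd.DataFrame(counts, index=ids, columns=meta["sample_id"].tolist()),
        unit="count",
    )
    return matrix, truth


def plant_modules(
    matrix: ExpressionMatrix,
    params: SimulationParams,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Overwrite selected transcripts with shared latent sample profiles.

    Module members get ``value = scale_g * exp(amplitude * z_s + eps)`` with a
    per-sample latent ``z`` common to the module and independent log-normal
    noise ``eps ~ N(0, module_noise_sd)``; with zero noise all within-module
    Pearson correlations are exactly 1.  Transcripts already labelled specific
    or DE in ``truth`` are never recruited into modules.
    """
    if params.n_modules * params.module_size > len(matrix.transcript_ids):
        raise ValueError("n_modules * module_size exceeds matrix size")
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if truth is None:
        truth = GroundTruth(transcript_ids=list(matrix.transcript_ids))

    reserved = set().union(*truth.specific_sets.values()) if truth.specific_sets else set()
    reserved |= truth.de_union()
    eligible = [t for t in matrix.transcript_ids if t not in reserved]
    need = params.n_modules * params.module_size
    if need > len(eligible):
        raise ValueError("not enough unlabelled transcripts for the requested modules")
    chosen = rng.choice(eligible, size=need, replace=False)

    data = matrix.data.copy()
    n_samples = data.shape[1]
    row_pos = {t: i for i, t in enumerate(data.index)}
    arr = data.to_numpy()
    for m in range(params.n_modules):
        members = chosen[m * params.module_size:(m + 1) * params.module_size]
        z = rng.normal(size=n_samples)
        for t in members:
            i = row_pos[t]
            scale = max(arr[i].mean(), 1.0)
            eps = (rng.normal(0.0, params.module_noise_sd, size=n_samples)
                   if params.module_noise_sd > 0 else 0.0)
            arr[i] = scale * np.exp(params.module_amplitude * z + eps)
            truth.module_assignment[t] = m
    out = ExpressionMatrix(pd.DataFrame(arr, index=data.index, columns=data.columns),
                           unit=matrix.unit)
    return out, truth


def generate_annotation_and_hits(
    truth: GroundTruth,
    n_go_terms: int,
    intervals: IntervalSet,
    seed: int,
    max_terms_per_transcript: int = 5,
    decoy_frac: float = 0.3,
    evalue_cutoff: float = 1e-5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random GO annotation plus alignment hits for the planted ACR set.

    Every ACR transcript receives one hit whose subject span lies inside a
    marker interval with e-value well under the cutoff; a ``decoy_frac``
    share of the remaining transcripts receive hits that must be removed
    downstream (outside every interval, or inside but above the e-value
    cutoff).  Hit tables use the 12-column tabular alignment layout.
    """
    if len(intervals) == 0:
        raise ValueError("interval set must be non-empty")
    rng = np.random.default_rng(seed)
    ids = list(truth.transcript_ids)

    terms = [f"GO:{i:07d}" for i in range(1, n_go_terms + 1)]
    go_rows = []
    for t in ids:
        k = rng.integers(0, max_terms_per_transcript + 1)
        if k == 0:
            continue
        assigned = rng.choice(terms, size=k, replace=False)
        truth.go_map[t] = set(assigned)
        go_rows.extend((t, term) for term in sorted(assigned))
    go_map = pd.DataFrame(go_rows, columns=["transcript_id", "term_id"])

    iv_list = list(intervals)
    hit_rows = []

    def _row(qid, chrom, s_start, s_end, evalue):
        aln = abs(s_end - s_start) + 1
        hit_rows.append((qid, chrom, round(rng.uniform(80, 100), 2), aln,
                         int(rng.integers(0, 5)), int(rng.integers(0, 3)),
                         1, aln, s_start, s_end, evalue,
                         round(rng.uniform(50, 500), 1)))

    for t in sorted(truth.acr_set):
        iv = iv_list[rng.integers(0, len(iv_list))]
        width = iv.end - iv.start
        span = int(min(max(width // 4, 1), 300))
        start = int(rng.integers(iv.start, max(iv.end - span, iv.start) + 1))
        end = min(start + span, iv.end)
        if rng.random() < 0.5:  # minus-strand hit
            start, end = end, start
        _row(t, iv.chrom, start, end, 10.0 ** rng.uniform(-30, -6))

    non_acr = [t for t in ids if t not in truth.acr_set]
    n_decoys = int(decoy_frac * len(non_acr))
    decoys = rng.choice(non_acr, size=n_decoys, replace=False) if n_decoys else []
    max_end = max(iv.end for iv in iv_list)
    for t in decoys:
        if rng.random() < 0.5:  # beyond every interval on a real chromosome
            iv = iv_list[rng.integers(0, len(iv_list))]
            start = int(max_end + 10_000 + rng.integers(0, 50_000))
            _row(t, iv.chrom, start, start + 200, 10.0 ** rng.uniform(-30, -6))
        else:  # inside an interval but too weak an e-value
            iv = iv_list[rng.integers(0, len(iv_list))]
            start = int(rng.integers(iv.start, iv.end + 1))
            _row(t, iv.chrom, start, min(start + 200, iv.end),
                 evalue_cutoff * 10.0 ** rng.uniform(0.5, 3))

    hits = pd.DataFrame(hit_rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore"])
    return go_map, hits
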