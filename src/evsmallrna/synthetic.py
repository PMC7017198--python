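"""Synthetic study-data generator.

Emulates the inputs of a cell-vs-EV small-RNA cargo experiment so the whole
pipeline is testable without any external download:

* multi-class ncRNA reference sequences spread over two "source databases"
  with verbatim cross-database duplicates (exercising deduplication),
* 51 nt single-end read libraries for parental-cell and EV samples whose
  per-feature counts are negative-binomial with planted per-miRNA log2 fold
  changes, 3' adapter / poly-A contamination and quality flags,
* qRT-PCR Ct tables with group-level expression shifts and dropout.

Every output is accompanied by a ground-truth table, and a fixed seed yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._io import write_fasta, write_fastq, write_tsv

# NEBNext small RNA 3' adapter prefix (the library chemistry the study used).
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

#: (class name, number of sequences, min length, max length) — lengths span
#: the biological ranges of each class; rRNA/snRNA deliberately include
#: sequences longer than twice the read length so the 50 %-coverage mapping
#: rule is exercised by construction.
DEFAULT_CLASSES: tuple[tuple[str, int, int, int], ...] = (
    ("miRNA", 200, 18, 25),
    ("snoRNA", 120, 60, 100),
    ("tRNA", 40, 70, 90),
    ("rRNA", 30, 80, 160),
    ("piRNA", 80, 26, 32),
    ("Mt_tRNA", 22, 65, 75),
    ("snRNA", 20, 90, 150),
)

#: Class composition of mappable reads per condition, taken from the averaged
#: replicate percentages of the study's PC3 cell / EV libraries.
_RAW_COMPOSITION = {
    "cell": {
        "snoRNA": 0.6050, "miRNA": 0.3238, "tRNA": 0.0393, "rRNA": 0.0166,
        "piRNA": 0.0060, "Mt_tRNA": 0.0090, "snRNA": 0.0003,
    },
    "ev": {
        "snoRNA": 0.0713, "miRNA": 0.6625, "tRNA": 0.0988, "rRNA": 0.1457,
        "piRNA": 0.0190, "Mt_tRNA": 0.0008, "snRNA": 0.0018,
    },
}
# published percentages carry rounding error; renormalize to exact unit mass
DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    cond: {cls: frac / sum(comp.values()) for cls, frac in comp.items()}
    for cond, comp in _RAW_COMPOSITION.items()
}


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study conditions: two replicates per condition,
    51 nt single-end reads, class compositions matching the published
    per-class read percentages, and planted four-fold (|log2FC| = 2) miRNA
    enrichment/depletion in EVs.
    """

    seed: int = 0
    classes: Sequence[tuple[str, int, int, int]] = DEFAULT_CLASSES
    duplicate_rate: float = 0.10
    class_composition: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_COMPOSITION.items()})
    n_features_enriched: int = 30
    n_features_depleted: int = 10
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.1
    library_size: int = 100_000
    n_replicates: int = 2
    read_length: int = 51
    adapter: str = DEFAULT_ADAPTER
    polya_prob: float = 0.2
    polya_len_range: tuple[int, int] = (5, 15)
    qual_low_prob: float = 0.05
    abundance_sigma: float = 1.0   # log-normal spread of within-class abundances
    depth_sigma: float = 0.15      # log-normal per-sample depth variation
    random_offset: bool = False    # read fragments anchored at feature 5' end by default
    conditions: tuple[str, str] = ("cell", "ev")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.classes:
            raise ConfigError("at least one ncRNA class is required")
        for name, n, lo, hi in self.classes:
            if n <= 0 or lo <= 0 or hi < lo:
                raise ConfigError(f"invalid class spec for {name!r}: n={n}, range=[{lo},{hi}]")
        for cond in self.conditions:
            comp = self.class_composition.get(cond)
            if comp is None:
                raise ConfigError(f"class_composition missing condition {cond!r}")
            total = sum(comp.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"class_composition[{cond!r}] sums to {total}, not 1")
        if set(self.adapter) - set("ACGT"):
            raise ConfigError(f"adapter contains non-ACGT characters: {self.adapter!r}")
        if not (0.0 <= self.duplicate_rate <= 1.0 and 0.0 <= self.polya_prob <= 1.0
                and 0.0 <= self.qual_low_prob <= 1.0):
            raise ConfigError("rates must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be non-negative")
        if self.read_length <= 0 or self.library_size <= 0 or self.n_replicates < 1:
            raise ConfigError("read_length, library_size, n_replicates must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classes"] = [list(c) for c in self.classes]
        d["polya_len_range"] = list(self.polya_len_range)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "classes" in d:
            d["classes"] = tuple(tuple(c) for c in d["classes"])
        if "polya_len_range" in d:
            d["polya_len_range"] = tuple(d["polya_len_range"])
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_reference(config: SimConfig, outdir: str | Path):
    """Generate source FASTA files plus the truth class map.

    Returns ``(sources, features)`` where ``sources`` is a list of
    ``(path, rna_class, source_name, priority)`` tuples ready for
    :func:`evsmallrna.reference.load_source_fasta` and ``features`` is a
    DataFrame with columns feature_id, rna_class, length, sequence.

    A fraction ``duplicate_rate`` of all sequences is copied verbatim into a
    second source database (written in lower-case RNA alphabet to exercise
    normalization) so reference compilation must deduplicate.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))

    rows = []
    seen: set[str] = set()
    for cls_name, n_seq, lo, hi in config.classes:
        for i in range(n_seq):
            length = int(rng.integers(lo, hi + 1))
            seq = _random_seq(rng, length)
            while seq in seen:  # reference sequences must be unique
                seq = _random_seq(rng, length)
            seen.add(seq)
            rows.append({"feature_id": f"{cls_name}-{i:04d}", "rna_class": cls_name,
                         "length": length, "sequence": seq})
    features = pd.DataFrame(rows)

    n_dup = int(round(config.duplicate_rate * len(features)))
    dup_idx = sorted(rng.choice(len(features), size=n_dup, replace=False)) if n_dup else []

    sources = []
    for cls_name, *_ in config.classes:
        sub = features[features.rna_class == cls_name]
        path = outdir / f"db_alpha_{cls_name}.fasta"
        write_fasta(zip(sub.feature_id, sub.sequence), path)
        sources.append((path, cls_name, "db_alpha", 1))

    dup = features.iloc[list(dup_idx)]
    for cls_name in dup.rna_class.unique():
        sub = dup[dup.rna_class == cls_name]
        path = outdir / f"db_beta_{cls_name}.fasta"
        # second database publishes the RNA alphabet in lower case
        write_fasta(((f"beta:{fid}", seq.replace("T", "U").lower())
                     for fid, seq in zip(sub.feature_id, sub.sequence)), path)
        sources.append((path, cls_name, "db_beta", 2))

    write_tsv(features, outdir / "features.truth.tsv",
              meta={"seed": config.seed, "n_features": len(features), "n_duplicated": n_dup})
    return sources, features


def simulate_counts(config: SimConfig, features: pd.DataFrame):
    """Draw latent per-sample NB counts and the ground-truth table.

    Per feature *i* in condition *c* and sample *j*:
    ``count ~ NB(mean = depth_j * q_ic, dispersion = nb_dispersion)`` with
    within-class log-normal abundances scaled so each condition's class
    totals follow ``class_composition`` in expectation. Planted miRNA
    features get ``q_ev = q_cell * 2**(±lfc_magnitude)`` before the EV
    abundance vector is renormalized to unit mass (fixed sequencing depth);
    the global renormalization constant is what median-of-ratios
    normalization later absorbs, so the planted lfc is the recoverable truth.

    Returns ``(truth, counts, condition_of)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    classes = features.rna_class.to_numpy()
    n_feat = len(features)

    weights = np.exp(rng.normal(0.0, config.abundance_sigma, size=n_feat))
    cond_a, cond_b = config.conditions
    q = {}
    for cond in config.conditions:
        comp = config.class_composition[cond]
        qc = np.zeros(n_feat)
        for cls_name in np.unique(classes):
            mask = classes == cls_name
            qc[mask] = comp.get(cls_name, 0.0) * weights[mask] / weights[mask].sum()
        q[cond] = qc

    mirna_idx = np.flatnonzero(classes == "miRNA")
    n_plant = config.n_features_enriched + config.n_features_depleted
    if n_plant > len(mirna_idx):
        raise ConfigError("more planted features requested than miRNA features available")
    planted = rng.choice(mirna_idx, size=n_plant, replace=False)
    planted_lfc = np.zeros(n_feat)
    planted_lfc[planted[:config.n_features_enriched]] = config.lfc_magnitude
    planted_lfc[planted[config.n_features_enriched:]] = -config.lfc_magnitude

    q_ev = q[cond_b] * np.exp2(planted_lfc)
    q_ev = q_ev / q_ev.sum()
    q[cond_b] = q_ev

    sample_names, condition_of, counts_cols = [], {}, {}
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            name = f"{cond}_{rep}"
            sample_names.append(name)
            condition_of[name] = cond
            depth = config.library_size * np.exp(rng.normal(0.0, config.depth_sigma))
            mean = depth * q[cond]
            counts_cols[name] = _nb_draw(rng, mean, config.nb_dispersion)

    counts = pd.DataFrame(counts_cols, index=features.feature_id)
    counts.index.name = "feature_id"

    truth = pd.DataFrame({
        "feature_id": features.feature_id,
        "rna_class": classes,
        "true_log2fc": planted_lfc,
        "planted": planted_lfc != 0,
        f"expected_mean_{cond_a}": config.library_size * q[cond_a],
        f"expected_mean_{cond_b}": config.library_size * q[cond_b],
    })
    return truth, counts, condition_of


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mu + dispersion * mu^2; Poisson limit at 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def synthesize_reads(config: SimConfig, counts: pd.DataFrame, features: pd.DataFrame,
                     outdir: str | Path) -> dict[str, Path]:
    """Emit one FASTQ per sample plus per-read truth tables.

    Each counted read is a sense-strand fragment of its source feature
    (anchored at the 5' end unless ``random_offset``), 3'-extended with a
    poly-A run (probability ``polya_prob``) and then the adapter, truncated
    to ``read_length``. A fraction ``qual_low_prob`` of reads receives a
    failing quality string (Q2 everywhere); the rest pass at Q37.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    seq_of = dict(zip(features.feature_id, features.sequence))
    read_len = config.read_length
    fastq_paths: dict[str, Path] = {}

    for sample in counts.columns:
        sample_counts = counts[sample]
        total = int(sample_counts.sum())
        order = rng.permutation(total)
        reads: list[tuple[str, str, str] | None] = [None] * total
        truth_rows: list[tuple[str, str]] = []
        pos = 0
        for feature_id, k in sample_counts.items():
            k = int(k)
            if k == 0:
                continue
            seq = seq_of[feature_id]
            for _ in range(k):
                if len(seq) <= read_len:
                    frag = seq
                elif config.random_offset:
                    off = int(rng.integers(0, len(seq) - read_len + 1))
                    frag = seq[off:off + read_len]
                else:
                    frag = seq[:read_len]
                tail = ""
                if config.polya_prob and rng.random() < config.polya_prob:
                    lo, hi = config.polya_len_range
                    tail = "A" * int(rng.integers(lo, hi + 1))
                read_seq = (frag + tail + config.adapter)[:read_len]
                if config.qual_low_prob and rng.random() < config.qual_low_prob:
                    qual = "#" * len(read_seq)   # Q2 across all bases
                else:
                    qual = "F" * len(read_seq)   # Q37
                idx = order[pos]
                read_id = f"{sample}:r{idx:07d}"
                reads[idx] = (read_id, read_seq, qual)
                truth_rows.append((read_id, feature_id))
                pos += 1
        fastq_paths[sample] = write_fastq(reads, outdir / f"{sample}.fastq")
        truth = pd.DataFrame(truth_rows, columns=["read_id", "feature_id"]).sort_values(
            "read_id", kind="mergesort")
        write_tsv(truth, outdir / f"{sample}.reads.truth.tsv",
                  meta={"sample": sample, "n_reads": total, "seed": config.seed})
    return fastq_paths


def simulate_ct_table(
    groups: tuple[str, str] = ("PCa", "BPH"),
    n_per_group: tuple[int, int] = (18, 7),
    target_shifts_log2: Mapping[str, float] | None = None,
    reference_targets: tuple[str, ...] = ("miR-20a-5p", "miR-28-5p"),
    n_technical: int = 2,
    sigma: float = 0.25,
    sample_sigma: float = 1.0,
    baseline_ct: float = 24.0,
    target_offsets: Mapping[str, float] | None = None,
    dropout: Mapping[tuple[str, str], float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a qRT-PCR Ct table with planted group shifts.

    Each sample has a latent input-amount baseline (reference-assay Ct is
    centred on it); a target's Ct is baseline + target offset − shift for
    members of ``groups[0]`` + technical noise. ``n_technical`` is 2 for the
    plasma/tissue design and 3 for the cell-line design. ``dropout`` maps
    (target, group) to a per-sample probability of the assay failing
    (recorded as undetected, i.e. Ct > 40).

    A shift of *s* log2 units produces an expected group difference of *s*
    on the 40−ΔCt scale.
    """
    if min(n_per_group) < 2:
        raise ConfigError("n_per_group must be >= 2 for group tests to be defined")
    shifts = dict(target_shifts_log2 or {})
    offsets = dict(target_offsets or {})
    dropout = dict(dropout or {})
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))

    targets = list(dict.fromkeys(list(reference_targets) + list(shifts)))
    rows = []
    for group, n in zip(groups, n_per_group):
        for s in range(1, n + 1):
            sample_id = f"{group}_{s:02d}"
            mu_sample = baseline_ct + rng.normal(0.0, sample_sigma)
            for target in targets:
                is_ref = target in reference_targets
                shift = 0.0 if is_ref else shifts.get(target, 0.0)
                delta = 0.0 if is_ref else offsets.get(target, 3.0)
                lost = (not is_ref) and rng.random() < dropout.get((target, group), 0.0)
                for tech in range(1, n_technical + 1):
                    if lost:
                        ct = np.nan
                    else:
                        ct = (mu_sample + delta
                              - (shift if group == groups[0] else 0.0)
                              + rng.normal(0.0, sigma))
                    rows.append({"sample_id": sample_id, "group": group,
                                 "bio_rep": s, "target": target,
                                 "tech_rep": tech, "ct": ct})
    return pd.DataFrame(rows)
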