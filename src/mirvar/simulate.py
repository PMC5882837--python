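"""Synthetic small-RNA-seq data with the statistical structure of a rodent
arcuate-nucleus miRNome study.

The generator produces three layers, each usable on its own:

* a miRNA *reference*: hairpin precursors, their -5p/-3p mature products
  ("partner" strands), and miR-gene-cluster membership;
* a *count matrix*: negative-binomial read counts for a multi-group,
  multi-replicate design, with per-library depth factors, lognormal
  co-varying factors shared by hypervariable clusters, and planted
  fold-changes of expression (with tunable partner-arm attenuation);
* raw *reads*: 4-line FASTQ per library, each read being a mature insert
  followed by a barcoded 3' adapter, plus an optional fraction of short
  junk inserts to exercise the length filter.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` children, so a fixed seed fixes every output
byte, and the count layer is reproducible whether or not reads are made.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import CountMatrix

__all__ = [
    "Hairpin",
    "MiRNAReference",
    "PlantedEffect",
    "SimConfig",
    "make_reference",
    "draw_baselines",
    "simulate_counts",
    "simulate_reads",
    "write_reference",
    "read_reference",
    "write_fastq",
]

DEFAULT_GROUPS = ("C-C", "C-HF", "HF-C", "HF-HF")
#: Placeholder 3' adapter tail; the real library chemistry is not modelled.
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
_NUCS = np.array(list("ACGT"))


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class ReferenceError(KeyError):
    """A name does not resolve against the miRNA reference."""


@dataclass(frozen=True)
class Hairpin:
    hairpin_id: str
    cluster_id: str
    mature_5p: str | None
    mature_3p: str | None
    seq_5p: str | None
    seq_3p: str | None

    @property
    def matures(self) -> list[tuple[str, str, str]]:
        """(name, arm, sequence) for each emitted strand."""
        out = []
        if self.mature_5p is not None:
            out.append((self.mature_5p, "5p", self.seq_5p))
        if self.mature_3p is not None:
            out.append((self.mature_3p, "3p", self.seq_3p))
        return out


class MiRNAReference:
    """Hairpins, mature strands and cluster membership.

    Mature names are unique and map to exactly one hairpin; a hairpin may
    emit one or two strands and, when two, they are mutual partners;
    cluster membership is a partition of hairpins (singletons allowed).
    """

    def __init__(self, hairpins: Sequence[Hairpin]):
        self.hairpins = list(hairpins)
        self._by_mature: dict[str, Hairpin] = {}
        self.sequences: dict[str, str] = {}
        self.arms: dict[str, str] = {}
        for hp in self.hairpins:
            for name, arm, seq in hp.matures:
                if name in self._by_mature:
                    raise ConfigurationError(f"duplicate mature name {name!r}")
                self._by_mature[name] = hp
                self.sequences[name] = seq
                self.arms[name] = arm
        self.clusters: dict[str, list[str]] = {}
        for hp in self.hairpins:
            self.clusters.setdefault(hp.cluster_id, []).append(hp.hairpin_id)

    @property
    def matures(self) -> list[str]:
        return list(self.sequences)

    def hairpin_of(self, mature: str) -> Hairpin:
        try:
            return self._by_mature[mature]
        except KeyError:
            raise ReferenceError(f"unknown mature miRNA {mature!r}") from None

    def partner_of(self, mature: str) -> str | None:
        """The strand from the opposite arm of the same hairpin, if emitted."""
        hp = self.hairpin_of(mature)
        names = [n for n, _, _ in hp.matures]
        others = [n for n in names if n != mature]
        return others[0] if others else None

    def cluster_of(self, mature: str) -> str:
        return self.hairpin_of(mature).cluster_id

    def cluster_members(self, cluster_id: str) -> list[str]:
        """All mature strands emitted by the cluster's hairpins."""
        ids = self.clusters.get(cluster_id)
        if ids is None:
            raise ReferenceError(f"unknown cluster {cluster_id!r}")
        by_id = {hp.hairpin_id: hp for hp in self.hairpins}
        return [n for hid in ids for n, _, _ in by_id[hid].matures]


@dataclass(frozen=True)
class PlantedEffect:
    """A fold-change of expression planted on one mature strand.

    ``fce`` multiplies the strand's expected expression in ``groups``; the
    partner strand (if any, and not itself planted) receives
    ``fce ** partner_attenuation`` so that arm concordance is tunable:
    1.0 gives perfectly concordant arms, 0.0 leaves the partner untouched.
    """

    groups: tuple[str, ...]
    fce: float
    partner_attenuation: float = 1.0

    def __post_init__(self):
        if self.fce <= 0:
            raise ConfigurationError("FCE multipliers must be positive")
        if not 0.0 <= self.partner_attenuation <= 1.0:
            raise ConfigurationError("partner_attenuation must be in [0, 1]")


@dataclass
class SimConfig:
    """Study design and generative parameters.

    Defaults emulate the profiled cohort: 4 diet groups x 6 biological
    replicates, a few hundred expressed miRNAs with lognormal baseline
    abundance, and negative-binomial counts with variance mu + alpha*mu^2.
    ``dispersion = 0`` is the noise-free limit: counts are the rounded
    expectations.
    """

    n_groups: int = 4
    n_replicates: int = 6
    n_hairpins: int = 230
    baseline_log_mean: float = math.log(150.0)
    baseline_log_sd: float = 1.5
    dispersion: float = 0.03
    depth_multipliers: Sequence[float] | None = None
    depth_log_sd: float = 0.25
    # cluster_id -> log-sd of the lognormal factor shared by members per library
    hypervariable_clusters: Mapping[str, float] = field(default_factory=dict)
    planted_effects: Mapping[str, PlantedEffect] = field(default_factory=dict)
    # hairpin_index -> cluster label; unlisted hairpins become singletons
    cluster_assignment: Mapping[int, str] = field(default_factory=dict)
    group_labels: Sequence[str] | None = None
    single_strand_fraction: float = 0.0
    junk_fraction: float = 0.0
    adapter3: str = DEFAULT_ADAPTER3
    barcodes: Mapping[str, str] | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_hairpins < 1:
            raise ConfigurationError("n_hairpins must be >= 1")
        if self.n_groups < 1 or self.n_replicates < 1:
            raise ConfigurationError("design must have >= 1 group and replicate")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if self.baseline_log_sd < 0 or self.depth_log_sd < 0:
            raise ConfigurationError("log-sds must be >= 0")
        for sd in self.hypervariable_clusters.values():
            if sd <= 0:
                raise ConfigurationError("shared-factor log-sd must be > 0")
        if not 0.0 <= self.junk_fraction < 1.0:
            raise ConfigurationError("junk_fraction must be in [0, 1)")

    @property
    def groups(self) -> list[str]:
        if self.group_labels is not None:
            labels = list(self.group_labels)
            if len(labels) != self.n_groups:
                raise ConfigurationError("group_labels length != n_groups")
            return labels
        if self.n_groups <= len(DEFAULT_GROUPS):
            return list(DEFAULT_GROUPS[: self.n_groups])
        return [f"G{i + 1}" for i in range(self.n_groups)]

    @property
    def libraries(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.groups for r in range(self.n_replicates)]

    def library_groups(self) -> pd.Series:
        return pd.Series(
            [g for g in self.groups for _ in range(self.n_replicates)],
            index=self.libraries,
            name="group",
        )

    def _child_rng(self, stream: int) -> np.random.Generator:
        # independent, reproducible streams per generator stage
        return np.random.default_rng(np.random.SeedSequence(self.rng_seed).spawn(8)[stream])


def _random_insert(rng: np.random.Generator, length: int) -> str:
    return "".join(_NUCS[rng.integers(0, 4, size=length)])


def _forbidden_motifs(config: SimConfig) -> list[str]:
    """Motifs mature sequences must avoid so that read processing is exact:
    the first 10 nt of the adapter and of every demultiplexing barcode."""
    motifs = [config.adapter3[:10]]
    if config.barcodes:
        for bc in config.barcodes.values():
            motifs.append(bc)
            motifs.append(bc[:10])
    return motifs


def make_reference(config: SimConfig) -> MiRNAReference:
    """Draw a synthetic miRNA reference.

    Sequences are random 20-24-nt strings, pairwise distinct even under
    the +/-2-nt 3'-end isomiR tolerance used by the quantifier, and free of
    adapter/barcode motifs so the read-level round trip is exact.
    """
    rng = config._child_rng(0)
    motifs = _forbidden_motifs(config)
    seen_keys: set[str] = set()

    def draw_seq() -> str:
        for _ in range(10_000):
            seq = _random_insert(rng, int(rng.integers(20, 25)))
            keys = {seq, seq[:-1], seq[:-2]}
            if any(m in seq for m in motifs):
                continue
            if keys & seen_keys:
                continue
            seen_keys.update(keys)
            return seq
        raise ConfigurationError("could not draw a distinct mature sequence")

    hairpins = []
    for i in range(config.n_hairpins):
        stem = f"mir-{i + 1:04d}"
        cluster = config.cluster_assignment.get(i, f"cl-{stem}")
        single = (
            config.single_strand_fraction > 0
            and rng.random() < config.single_strand_fraction
        )
        if single:
            arm = "5p" if rng.random() < 0.5 else "3p"
            s = draw_seq()
            hairpins.append(
                Hairpin(
                    hairpin_id=stem,
                    cluster_id=cluster,
                    mature_5p=f"{stem}-5p" if arm == "5p" else None,
                    mature_3p=f"{stem}-3p" if arm == "3p" else None,
                    seq_5p=s if arm == "5p" else None,
                    seq_3p=s if arm == "3p" else None,
                )
            )
        else:
            hairpins.append(
                Hairpin(
                    hairpin_id=stem,
                    cluster_id=cluster,
                    mature_5p=f"{stem}-5p",
                    mature_3p=f"{stem}-3p",
                    seq_5p=draw_seq(),
                    seq_3p=draw_seq(),
                )
            )
    return MiRNAReference(hairpins)


def draw_baselines(reference: MiRNAReference, config: SimConfig) -> pd.Series:
    """Per-mature expected baseline expression (lognormal), deterministic
    under the config seed and independent of later sampling stages."""
    rng = config._child_rng(1)
    names = reference.matures
    vals = np.exp(rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(names)))
    return pd.Series(vals, index=names, name="baseline")


def _depths(config: SimConfig) -> pd.Series:
    libs = config.libraries
    if config.depth_multipliers is not None:
        d = np.asarray(config.depth_multipliers, dtype=float)
        if d.shape != (len(libs),):
            raise ConfigurationError("depth_multipliers length != number of libraries")
        if (d <= 0).any():
            raise ConfigurationError("depth multipliers must be positive")
        return pd.Series(d, index=libs)
    rng = config._child_rng(2)
    if config.depth_log_sd == 0:
        return pd.Series(1.0, index=libs)
    return pd.Series(np.exp(rng.normal(0.0, config.depth_log_sd, len(libs))), index=libs)


def expected_means(
    reference: MiRNAReference,
    config: SimConfig,
    baselines: pd.Series | None = None,
) -> pd.DataFrame:
    """Expectation matrix mu[miRNA, library] *before* the hypervariable
    cluster factors (which are mean-one multiplicative noise)."""
    if baselines is None:
        baselines = draw_baselines(reference, config)
    depths = _depths(config)
    groups = config.library_groups()
    mu = pd.DataFrame(
        np.outer(baselines.to_numpy(), depths.to_numpy()),
        index=baselines.index,
        columns=depths.index,
    )
    mult = pd.DataFrame(1.0, index=mu.index, columns=config.groups)
    for name, eff in config.planted_effects.items():
        if name not in reference.sequences:
            raise ReferenceError(f"planted effect on unknown mature {name!r}")
        for g in eff.groups:
            if g not in mult.columns:
                raise ConfigurationError(f"planted effect names unknown group {g!r}")
            mult.loc[name, g] *= eff.fce
            partner = reference.partner_of(name)
            if partner is not None and partner not in config.planted_effects:
                mult.loc[partner, g] *= eff.fce**eff.partner_attenuation
    for lib in mu.columns:
        mu[lib] *= mult[groups[lib]]
    return mu


def simulate_counts(
    reference: MiRNAReference,
    config: SimConfig,
    baselines: pd.Series | None = None,
) -> CountMatrix:
    """Sample a miRNA x library count matrix.

    Counts are NB(mu, alpha) with variance mu + alpha*mu^2, where mu is
    baseline x library depth x shared cluster factor x planted FCE; members
    of a hypervariable cluster share one lognormal factor draw per library,
    producing the co-variation seen across biological replicates. With
    ``dispersion == 0`` counts are deterministic rounded expectations.
    """
    mu = expected_means(reference, config, baselines)
    rng = config._child_rng(3)
    # shared mean-one lognormal factor per (cluster, library)
    for cluster_id, log_sd in config.hypervariable_clusters.items():
        members = reference.cluster_members(cluster_id)
        factors = np.exp(rng.normal(-0.5 * log_sd**2, log_sd, mu.shape[1]))
        mu.loc[members] = mu.loc[members].to_numpy() * factors[None, :]
    m = mu.to_numpy()
    if config.dispersion == 0:
        counts = np.rint(m).astype(np.int64)
    else:
        n = 1.0 / config.dispersion
        counts = rng.negative_binomial(n, n / (n + m)).astype(np.int64)
    frame = pd.DataFrame(counts, index=mu.index, columns=mu.columns)
    return CountMatrix(frame, config.library_groups())


# ---------------------------------------------------------------------------
# read-level simulation


def simulate_reads(
    counts: CountMatrix,
    reference: MiRNAReference,
    adapter3: str | None = None,
    barcodes: Mapping[str, str] | None = None,
    config: SimConfig | None = None,
) -> dict[str, list[tuple[str, str, str]]]:
    """Expand a count matrix into per-library FASTQ records.

    Each read is ``mature insert + library barcode + 3' adapter tail`` with
    a constant quality line; the multiplicity of a mature sequence in a
    library equals its count cell. ``config.junk_fraction`` of extra short
    (<15 nt) inserts is spiked in to exercise the length filter.

    Returns ``{library: [(read_id, sequence, quality), ...]}``.
    """
    if config is None:
        config = SimConfig(n_hairpins=1)
    if adapter3 is None:
        adapter3 = config.adapter3
    if barcodes is None:
        barcodes = config.barcodes or default_barcodes(list(counts.counts.columns))
    _check_barcodes(barcodes)
    missing = [lib for lib in counts.counts.columns if lib not in barcodes]
    if missing:
        raise ConfigurationError(f"no barcode for libraries {missing}")
    rng = config._child_rng(4)
    out: dict[str, list[tuple[str, str, str]]] = {}
    for lib in counts.counts.columns:
        tail = barcodes[lib] + adapter3
        records = []
        serial = 0
        for mature, c in counts.counts[lib].items():
            seq = reference.sequences[mature]
            for _ in range(int(c)):
                serial += 1
                full = seq + tail
                records.append((f"{lib}:{serial}", full, "I" * len(full)))
        n_junk = int(round(config.junk_fraction * len(records)))
        for _ in range(n_junk):
            serial += 1
            insert = _random_insert(rng, int(rng.integers(5, 15)))
            full = insert + tail
            records.append((f"{lib}:{serial}", full, "I" * len(full)))
        # shuffle so read order carries no signal
        order = rng.permutation(len(records))
        out[lib] = [records[i] for i in order]
    return out


def default_barcodes(libraries: Sequence[str]) -> dict[str, str]:
    """Deterministic pairwise-distinct 11-nt barcodes, one per library."""
    rng = np.random.default_rng(20180328)
    seen: set[str] = set()
    out = {}
    for lib in libraries:
        while True:
            bc = _random_insert(rng, 11)
            if bc not in seen and not any(bc[:10] in b or b[:10] in bc for b in seen):
                seen.add(bc)
                out[lib] = bc
                break
    return out


def _check_barcodes(barcodes: Mapping[str, str]) -> None:
    vals = list(barcodes.values())
    if any(len(b) != 11 for b in vals):
        raise ConfigurationError("barcodes must be 11 nt")
    if len(set(vals)) != len(vals):
        raise ConfigurationError("duplicate barcodes")


# ---------------------------------------------------------------------------
# on-disk formats


def write_reference(reference: MiRNAReference, fasta_path, sidecar_path) -> None:
    """Mature sequences as FASTA plus a TSV sidecar
    (mature_name, hairpin_id, cluster_id, arm)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in reference.sequences.items()
    ]
    seqio_write(records, str(fasta_path), "fasta")
    rows = []
    for hp in reference.hairpins:
        for name, arm, _ in hp.matures:
            rows.append((name, hp.hairpin_id, hp.cluster_id, arm))
    pd.DataFrame(rows, columns=["mature_name", "hairpin_id", "cluster_id", "arm"]).to_csv(
        sidecar_path, sep="\t", index=False
    )


def read_reference(fasta_path, sidecar_path) -> MiRNAReference:
    from Bio.SeqIO import parse as seqio_parse

    seqs = {rec.id: str(rec.seq) for rec in seqio_parse(str(fasta_path), "fasta")}
    side = pd.read_csv(sidecar_path, sep="\t")
    hairpins = []
    for hid, sub in side.groupby("hairpin_id", sort=False):
        kw = dict(mature_5p=None, mature_3p=None, seq_5p=None, seq_3p=None)
        for _, row in sub.iterrows():
            name = row["mature_name"]
            if name not in seqs:
                raise ReferenceError(f"{name!r} missing from FASTA")
            kw[f"mature_{row['arm']}"] = name
            kw[f"seq_{row['arm']}"] = seqs[name]
        hairpins.append(Hairpin(hairpin_id=hid, cluster_id=sub["cluster_id"].iloc[0], **kw))
    return MiRNAReference(hairpins)


def write_fastq(records: Sequence[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
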