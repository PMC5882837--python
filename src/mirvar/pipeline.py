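"""End-to-end orchestration: counts (simulated, loaded, or derived from
FASTQ) -> normalization -> variability screen -> differential expression
-> partner/cluster concordance, with TSV outputs, a run log and a
machine-readable summary.

Within-group variability is screened on group-scope normalization (each
group's six profiles normalized together); between-group comparisons use
global-scope normalization (all libraries normalized together). Every
stage logs its row accounting; re-running with the same configuration and
seed reproduces every output byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import concordance as conc
from . import differential as diff
from . import normalize as norm
from . import readproc, simulate, variability

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    out_dir: str | Path = "results"
    # input layers (exactly one of: simulate config, counts TSV, FASTQ dir)
    sim: simulate.SimConfig | None = None
    counts_tsv: str | None = None
    fastq_dir: str | None = None
    reference_fasta: str | None = None
    reference_sidecar: str | None = None
    barcodes_tsv: str | None = None
    adapter3: str = simulate.DEFAULT_ADAPTER3
    write_fastq: bool = False
    # thresholds
    min_len: int = 16
    expression_threshold: float = 10.0
    alpha_primary: float = 1.0e-2
    alpha_secondary: float = 5.0e-2
    test: str = "nb"
    tested_rule: str = "union"
    screen_scope: str = "group"
    reference_group: str | None = None
    repeated_comparisons: tuple[str, str] | None = None

    def __post_init__(self):
        if not 0 < self.alpha_primary <= self.alpha_secondary <= 1:
            raise PipelineError("need 0 < alpha_primary <= alpha_secondary <= 1")
        if self.expression_threshold < 0 or self.min_len < 1:
            raise PipelineError("thresholds out of range")


@dataclass
class PipelineResult:
    reference: simulate.MiRNAReference | None
    counts: norm.CountMatrix
    vartable: variability.VariabilityTable
    de: dict[str, pd.DataFrame]
    pairs: dict[str, conc.PartnerPairTable]
    repeated: conc.RepeatedImpactSet | None
    summary: dict = field(default_factory=dict)


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        stamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        self.lines.append(f"{stamp}  {msg}")

    def flush(self) -> None:
        self.path.write_text("\n".join(self.lines) + "\n")


def _stage(log: _Log, name: str):
    class _Ctx:
        def __enter__(self):
            log.info(f"stage {name}: start")
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                log.info(f"stage {name}: FAILED ({exc})")
                log.flush()
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info(f"stage {name}: done")
            return False

    return _Ctx()


def _acquire_counts(
    config: PipelineConfig, out: Path, log: _Log
) -> tuple[simulate.MiRNAReference | None, norm.CountMatrix]:
    if config.sim is not None:
        with _stage(log, "simulate"):
            ref = simulate.make_reference(config.sim)
            cm = simulate.simulate_counts(ref, config.sim)
            simulate.write_reference(ref, out / "reference.fa", out / "reference.tsv")
            norm.write_count_matrix(cm, out / "counts_raw.tsv")
            log.info(
                f"simulate: {len(ref.matures)} matures x {cm.counts.shape[1]} libraries"
            )
            if config.write_fastq or config.fastq_dir:
                reads = simulate.simulate_reads(cm, ref, config=config.sim)
                fq = Path(config.fastq_dir) if config.fastq_dir else out / "fastq"
                fq.mkdir(parents=True, exist_ok=True)
                for lib, recs in reads.items():
                    simulate.write_fastq(recs, fq / f"{lib}.fastq")
                log.info(f"simulate: wrote FASTQ for {len(reads)} libraries")
        return ref, cm
    if config.counts_tsv is not None:
        with _stage(log, "load-counts"):
            cm = norm.read_count_matrix(config.counts_tsv)
            ref = None
            if config.reference_fasta and config.reference_sidecar:
                ref = simulate.read_reference(
                    config.reference_fasta, config.reference_sidecar
                )
            log.info(f"load-counts: {cm.counts.shape[0]} x {cm.counts.shape[1]}")
        return ref, cm
    if config.fastq_dir is not None:
        with _stage(log, "process-reads"):
            if not (config.reference_fasta and config.reference_sidecar):
                raise PipelineError("FASTQ processing needs a reference")
            if not config.barcodes_tsv:
                raise PipelineError("FASTQ processing needs a barcode table")
            ref = simulate.read_reference(
                config.reference_fasta, config.reference_sidecar
            )
            bc_frame = pd.read_csv(config.barcodes_tsv, sep="\t")
            barcodes = dict(zip(bc_frame["library"], bc_frame["barcode"]))
            groups = dict(zip(bc_frame["library"], bc_frame["group"]))
            profiles = {}
            for lib, bc in barcodes.items():
                batch = readproc.read_fastq(Path(config.fastq_dir) / f"{lib}.fastq")
                batch.library = lib
                profile, acc = readproc.process_library(
                    batch, ref, bc + config.adapter3, min_len=config.min_len
                )
                profiles[lib] = profile
                log.info(
                    f"process-reads {lib}: in={acc.n_input} short={acc.n_discarded_short}"
                    f" assigned={acc.n_assigned} unassigned={acc.n_unassigned}"
                )
            cm = norm.CountMatrix(pd.DataFrame(profiles), pd.Series(groups))
        return ref, cm
    raise PipelineError("no input layer configured (sim / counts_tsv / fastq_dir)")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "run.log")

    reference, cm = _acquire_counts(config, out, log)
    groups = cm.group_names
    ref_group = config.reference_group or groups[0]
    if ref_group not in groups:
        raise PipelineError(f"reference group {ref_group!r} absent")

    with _stage(log, "normalize"):
        screen_cm = norm.CountMatrix(cm.counts, cm.groups)
        norm.normalize(screen_cm, scope=config.screen_scope)
        norm.normalize(cm, scope="global")
        cm.size_factors.to_frame().to_csv(out / "size_factors.tsv", sep="\t")
        expressed = {
            g: norm.expression_filter(screen_cm, g, config.expression_threshold)
            for g in groups
        }
        for g in groups:
            log.info(f"normalize: {len(expressed[g])} expressed miRNAs in {g}")

    with _stage(log, "variability"):
        vt = variability.variability_table(screen_cm, expressed)
        variability.hypervariability_screen(vt, ref_group)
        vt.summary.to_csv(out / "variability_summary.tsv", sep="\t")
        flagged_any = vt.flags.index[vt.flags.any(axis=1)]
        vt.stats.loc[flagged_any, "MAX/MIN"].to_csv(
            out / "hypervariable_maxmin.tsv", sep="\t"
        )
        scatter = pd.concat(
            {g: vt.stats.xs(g, axis=1, level=1) for g in groups}, axis=1
        )
        scatter.to_csv(out / "variability_scatter.tsv", sep="\t")
        log.info(
            f"variability: threshold {vt.threshold:.3g} from {ref_group};"
            f" flagged per group "
            + ", ".join(f"{g}={int(vt.summary.loc['n_hypervariable', g])}" for g in groups)
        )

    de: dict[str, pd.DataFrame] = {}
    with _stage(log, "differential"):
        for g in groups:
            if g == ref_group:
                continue
            table = diff.de_table(
                cm,
                ref_group,
                g,
                test=config.test,
                expression_threshold=config.expression_threshold,
                tested_rule=config.tested_rule,
                alpha_primary=config.alpha_primary,
                alpha_secondary=config.alpha_secondary,
            )
            de[g] = table
            table.to_csv(out / f"de_{g}_vs_{ref_group}.tsv", sep="\t")
            diff.volcano_frame(table).to_csv(
                out / f"volcano_{g}_vs_{ref_group}.tsv", sep="\t"
            )
            log.info(
                f"differential {g} vs {ref_group} [{config.test}]: m={table.attrs['m']}"
                f" tier1={(table['tier'] == 1).sum()} tier2={(table['tier'] == 2).sum()}"
            )

    pairs: dict[str, conc.PartnerPairTable] = {}
    repeated: conc.RepeatedImpactSet | None = None
    with _stage(log, "concordance"):
        if reference is not None:
            for g, table in de.items():
                pt = conc.pair_partners(table, reference)
                pairs[g] = pt
                pt.pairs.to_csv(out / f"pairs_{g}_vs_{ref_group}.tsv", sep="\t", index=False)
                log.info(
                    f"concordance {g}: {len(pt.pairs)} pairs,"
                    f" {len(pt.partnerless)} partnerless, R2={pt.r2:.3f}"
                    if len(pt.pairs) >= 3
                    else f"concordance {g}: {len(pt.pairs)} pairs"
                )
            rc = config.repeated_comparisons
            if rc is None and len(de) >= 2:
                rc = tuple(list(de)[-2:])
            if rc is not None and all(g in de for g in rc):
                confirmed = conc.confirm_by_partner(pairs[rc[0]], config.alpha_secondary)
                repeated = conc.repeated_impact(
                    de[rc[0]],
                    de[rc[1]],
                    confirmed,
                    reference,
                    alpha_secondary=config.alpha_secondary,
                )
                repeated.fces.to_csv(out / "repeated_impact_fces.tsv", sep="\t")
                log.info(
                    f"concordance repeated-impact {rc[0]}&{rc[1]}:"
                    f" {len(repeated.members)} members, cross-R2={repeated.cross_r2:.3f}"
                )
        else:
            log.info("concordance: skipped (no hairpin reference)")

    summary = {
        "groups": groups,
        "reference_group": ref_group,
        "test": config.test,
        "n_expressed": {g: int(len(expressed[g])) for g in groups},
        "hypervariability_threshold": round(float(vt.threshold), 6),
        "n_hypervariable": {
            g: int(vt.summary.loc["n_hypervariable", g]) for g in groups
        },
        "pct_hypervariable": {
            g: float(vt.summary.loc["pct_hypervariable", g]) for g in groups
        },
        "tier1": {g: int((t["tier"] == 1).sum()) for g, t in de.items()},
        "tier2": {g: int((t["tier"] == 2).sum()) for g, t in de.items()},
        "tested_m": {g: int(t.attrs["m"]) for g, t in de.items()},
        "partner_r2": {
            g: (round(p.r2, 6) if len(p.pairs) >= 3 and not math.isnan(p.r2) else None)
            for g, p in pairs.items()
        },
        "repeated_impact_members": repeated.members if repeated else [],
        "repeated_impact_cross_r2": (
            round(repeated.cross_r2, 6)
            if repeated and not math.isnan(repeated.cross_r2)
            else None
        ),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("pipeline: complete")
    log.flush()
    return PipelineResult(
        reference=reference,
        counts=cm,
        vartable=vt,
        de=de,
        pairs=pairs,
        repeated=repeated,
        summary=summary,
    )
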