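"""End-to-end pipeline: align -> qc -> call -> stats/ca/cluster -> plots.

``run_pipeline`` wires the library stages together, writes each stage's
outputs under a named subdirectory and finishes with a manifest (config echo,
per-stage counts, output checksums) so reruns are verifiable: identical
inputs and seed give identical manifest checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import align as _align
from . import calls as _calls
from . import plotting as _plotting
from . import qc as _qc
from . import stats as _stats
from .io import read_fasta, read_gff_sequences

logger = logging.getLogger("methkit")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    reference: str
    clones: str
    outdir: str
    match_score: float = 1.0
    mismatch_score: float = -1.0
    bisulfite_tc_score: float = 1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    max_conversion_ratio: float = 0.1
    min_identity: float = 0.8
    cooccurrence_mode: str = "correlation"
    linkage: str = "complete"
    lollipop_mode: str = "genomic"
    plot_format: str = "png"
    seed: int = 0
    verbosity: str = "INFO"

    def scheme(self) -> _align.SubstitutionScheme:
        return _align.SubstitutionScheme(
            match_score=self.match_score,
            mismatch_score=self.mismatch_score,
            bisulfite_tc_score=self.bisulfite_tc_score,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Flat key=value config file; '#' comments; flags override file."""
    values: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value")
        key, val = (s.strip() for s in line.split("=", 1))
        values[key] = val.strip("\"'")
    values.update({k: v for k, v in overrides.items() if v is not None})
    fields = RunConfig.__dataclass_fields__
    unknown = set(values) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    coerced = {}
    for key, val in values.items():
        typ = fields[key].type
        if isinstance(val, str) and typ in ("float", "int"):
            val = float(val) if typ == "float" else int(val)
        coerced[key] = val
    return RunConfig(**coerced)


def _setup_logging(outdir: Path, verbosity: str) -> None:
    logger.setLevel(verbosity)
    logger.handlers.clear()
    fmt = logging.Formatter(
        "%(asctime)s [%(stage)s] %(message)s", "%H:%M:%S"
    )
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(outdir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_sequences(path: str):
    if str(path).endswith((".gff", ".gff3")):
        return read_gff_sequences(path)
    return read_fasta(path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Raises on any stage error after writing a FAILED marker, so partial
    outputs stay inspectable and the CLI exits non-zero.
    """
    ref_path = Path(cfg.reference)
    clones_path = Path(cfg.clones)
    for p in (ref_path, clones_path):
        if not p.exists():
            raise FileNotFoundError(f"input not found: {p}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, cfg.verbosity)
    (outdir / "config.json").write_text(json.dumps(asdict(cfg), indent=1))

    try:
        return _run_stages(cfg, outdir)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise


def _run_stages(cfg: RunConfig, outdir: Path) -> dict:
    scheme = cfg.scheme()
    counts: dict = {}

    ref_records = _read_sequences(cfg.reference)
    if len(ref_records) != 1:
        raise ValueError("reference file must contain exactly one sequence")
    ref = _calls.find_cpg_sites(ref_records[0])
    clones = _read_sequences(cfg.clones)
    _log("read", f"reference {ref.id}: {len(ref.bases)} bp, "
         f"{len(ref.cpg_positions)} CpG sites; {len(clones)} clone(s)")
    counts["n_clones_in"] = len(clones)
    counts["n_cpg_sites"] = len(ref.cpg_positions)

    align_dir = outdir / "align"
    align_dir.mkdir(exist_ok=True)
    alignments = _align.align_clones(ref_records[0], clones, scheme)
    _align.alignments_to_tsv(alignments, align_dir / "alignments.tsv")
    _align.alignments_to_fasta(alignments, align_dir / "alignments.fasta")
    _log("align", f"{len(alignments)} clone(s) oriented and aligned")

    qc_dir = outdir / "qc"
    qc_dir.mkdir(exist_ok=True)
    reports = [_qc.qc_clone(a, ref.bases, ref.cpg_positions, scheme)
               for a in alignments]
    passed, failed = _qc.apply_gates(
        reports, cfg.max_conversion_ratio, cfg.min_identity)
    _qc.reports_to_frame(reports).to_csv(qc_dir / "qc.tsv", sep="\t",
                                         index=False)
    (qc_dir / "qc_summary.txt").write_text(_qc.summary_text(reports) + "\n")
    _log("qc", f"{len(passed)}/{len(reports)} clone(s) passed QC")
    counts["n_passed_qc"] = len(passed)
    passed_ids = {r.clone_id for r in passed}
    kept = [a for a in alignments if a.clone_id in passed_ids]

    call_dir = outdir / "call"
    call_dir.mkdir(exist_ok=True)
    ds = _calls.assemble_dataset(kept, ref)
    ds.to_json(call_dir / "dataset.json")
    ds.to_tsv(call_dir / "matrix.tsv")
    _log("call", f"{ds.n_clones} x {ds.n_sites} methylation matrix")
    counts["matrix_shape"] = [ds.n_clones, ds.n_sites]

    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    summary = _stats.methylation_summary(ds)
    summary.to_csv(stats_dir / "summary.tsv", sep="\t")
    cooc = _stats.cooccurrence(ds, mode=cfg.cooccurrence_mode)
    cooc.to_frame().to_csv(stats_dir / "cooccurrence.tsv", sep="\t")
    clust = None
    if ds.n_clones >= 2 and ds.n_sites >= 2:
        try:
            clust = _stats.hamming_bicluster(ds, linkage=cfg.linkage)
        except ValueError as exc:
            _log("stats", f"biclustering skipped: {exc}")
    ca = _stats.correspondence_analysis(ds)
    np.savetxt(stats_dir / "ca_row_coords.tsv", ca.row_coords,
               delimiter="\t")
    np.savetxt(stats_dir / "ca_col_coords.tsv", ca.col_coords,
               delimiter="\t")
    (stats_dir / "ca_inertia.json").write_text(json.dumps({
        "principal_inertias": ca.principal_inertias.tolist(),
        "percent_inertia": ca.percent_inertia.tolist(),
        "total_inertia": ca.total_inertia,
    }, indent=1))
    _log("stats", "summary, co-occurrence, clustering, CA written; "
         f"CA percent inertia {np.round(ca.percent_inertia, 2).tolist()}")
    counts["ca_percent_inertia"] = [round(float(v), 2)
                                    for v in ca.percent_inertia]

    plot_dir = outdir / "plots"
    plot_dir.mkdir(exist_ok=True)
    ext = cfg.plot_format
    _plotting.plot_lollipop(ds, summary, cooc,
                            plot_dir / f"lollipop.{ext}",
                            mode=cfg.lollipop_mode)
    _plotting.plot_cooccurrence_matrix(cooc, plot_dir / f"cooccurrence.{ext}")
    if len(ca.percent_inertia) >= 1:
        _plotting.plot_ca_biplot(ca, plot_dir / f"ca_biplot.{ext}")
    if clust is not None:
        _plotting.plot_cluster_heatmap(ds, clust,
                                       plot_dir / f"heatmap.{ext}")
    _log("plot", f"plots written to {plot_dir}")

    manifest = {
        "config": asdict(cfg),
        "counts": counts,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p)
            for p in sorted(outdir.rglob("*"))
            if p.is_file() and p.suffix in (".tsv", ".json", ".fasta", ".txt")
            # config echo embeds the outdir path; it is provenance, not output
            and p.name not in ("manifest.json", "config.json")
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    _log("done", "manifest written")
    return manifest
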