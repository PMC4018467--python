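"""End-to-end orchestration: simulate -> partition -> scan -> compress ->
cluster -> compare, with per-stage artifacts and a checksummed manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml
from Bio import SeqIO

from . import __version__
from .distances import distance_matrix, length_correlation, profile_panel, profiles_table
from .panel import (
    PanelConfig,
    default_panel_config,
    generate_panel,
    pad_to_alignment,
    read_fasta,
    str_sector,
    write_fasta,
)
from .partition import DEFAULT_SCHEME, concat_sectors, identity_report, partition_alignment
from .repeats import decompose_str, find_repeats, runs_table, str_report
from .trees import bootstrap_support, compare_groupings, hclust, p_distance_matrix, to_newick


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one orchestrated run needs; seed reaches every stage."""

    out_dir: str = "drbstr_run"
    input_fasta: str | None = None  # None -> simulate the default panel
    seed: int = 0
    tandem_factor: int = 100
    metric: str = "manhattan"
    mode: str = "size"
    linkage: str = "complete"
    bootstrap_n: int = 100
    support_threshold: float = 70.0
    min_mono: int = 12
    min_multi: int = 4
    max_gap: int = 4
    min_purity: float = 0.85

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": asdict(config),
        "stages": {},
    }

    def record_stage(name: str, files: list[Path]) -> None:
        manifest["stages"][name] = {
            str(p.relative_to(out)): _sha256(p) for p in files
        }

    # -- stage 1: panel ----------------------------------------------------
    try:
        panel_cfg = default_panel_config(seed=config.seed)
        if config.input_fasta is None:
            records, truth = generate_panel(panel_cfg)
        else:
            records = read_fasta(config.input_fasta)
            truth = None
        fasta = out / "panel.fasta"
        write_fasta(records, fasta)
        files = [fasta]
        if truth is not None:
            tpath = out / "truth.tsv"
            truth.to_csv(tpath, sep="\t", index=False)
            files.append(tpath)
        record_stage("panel", files)
    except Exception as exc:
        raise StageError("panel", exc) from exc

    # -- stage 2: partition ------------------------------------------------
    try:
        alignment = pad_to_alignment(records, panel_cfg)
        part = partition_alignment(alignment, DEFAULT_SCHEME)
        files = []
        for name in DEFAULT_SCHEME.names:
            p = out / f"sector_{name}.fasta"
            SeqIO.write(part[name], str(p), "fasta")
            files.append(p)
        ident = identity_report(part)
        ipath = out / "identity.tsv"
        ident.to_csv(ipath, sep="\t", index=False, float_format="%.4f")
        files.append(ipath)
        record_stage("partition", files)
    except Exception as exc:
        raise StageError("partition", exc) from exc

    # -- stage 3: repeat scan ----------------------------------------------
    try:
        scan_kwargs = dict(
            min_mono=config.min_mono,
            min_multi=config.min_multi,
            max_gap=config.max_gap,
            min_purity=config.min_purity,
        )
        strs = [(r.id, str_sector(r, panel_cfg)) for r in records]
        annotations, run_frames = [], []
        for rid, s in strs:
            runs = find_repeats(s, **scan_kwargs)
            run_frames.append(runs_table(rid, runs))
            annotations.append(decompose_str(s, runs, seq_id=rid))
        import pandas as pd

        rpath = out / "repeat_runs.tsv"
        nonempty = [f for f in run_frames if not f.empty] or run_frames[:1]
        pd.concat(nonempty, ignore_index=True).to_csv(rpath, sep="\t", index=False)
        apath = out / "str_annotations.tsv"
        str_report(annotations).to_csv(apath, sep="\t", index=False)
        record_stage("scan", [rpath, apath])
    except Exception as exc:
        raise StageError("scan", exc) from exc

    # -- stage 4: compression distances --------------------------------------
    try:
        profiles = profile_panel(strs, tandem_factor=config.tandem_factor)
        ppath = out / "profiles.tsv"
        profiles_table(profiles).to_csv(ppath, sep="\t", index=False)
        dm = distance_matrix(profiles, metric=config.metric, mode=config.mode)
        dpath = out / "distances.csv"
        dm.to_dataframe().to_csv(dpath, float_format="%.6f")
        phypath = out / "distances.phy"
        phypath.write_text(dm.to_phylip())
        manifest["length_correlation_r2"] = round(length_correlation(profiles), 6)
        record_stage("compressdist", [ppath, dpath, phypath])
    except Exception as exc:
        raise StageError("compressdist", exc) from exc

    # -- stage 5: trees ------------------------------------------------------
    try:
        dend = hclust(dm, linkage=config.linkage)
        files = []
        cpath = out / f"str_{config.linkage}_dendrogram.nwk"
        cpath.write_text(dend.to_newick() + "\n")
        files.append(cpath)
        sector_trees = {}
        for label, names in (("exon2", ("exon2",)), ("intron2AB", ("intron2A", "intron2B"))):
            sub = concat_sectors(part, names)
            tree = bootstrap_support(
                sub,
                n=config.bootstrap_n,
                seed=config.seed,
                support_threshold=config.support_threshold,
            )
            sector_trees[label] = tree
            npath = out / f"{label}_nj.nwk"
            npath.write_text(to_newick(tree) + "\n")
            files.append(npath)
        record_stage("trees", files)
    except Exception as exc:
        raise StageError("trees", exc) from exc

    # -- stage 6: concordance ------------------------------------------------
    try:
        truth_map = (
            dict(zip(truth["id"], truth["lineage"])) if truth is not None else None
        )
        k = len(set(truth_map.values())) if truth_map else 5
        rows = []
        pairs = [
            ("str_vs_exon2", dend, sector_trees["exon2"]),
            ("str_vs_intron2AB", dend, sector_trees["intron2AB"]),
            ("exon2_vs_intron2AB", sector_trees["exon2"], sector_trees["intron2AB"]),
        ]
        for name, a, b in pairs:
            cmpres = compare_groupings(a, b, truth=truth_map, k=k)
            rows.append(
                (
                    name,
                    cmpres.shared_bipartitions,
                    cmpres.n_bipartitions_a,
                    cmpres.n_bipartitions_b,
                    round(cmpres.ari, 4),
                    "" if cmpres.ari_a_truth is None else round(cmpres.ari_a_truth, 4),
                    "" if cmpres.ari_b_truth is None else round(cmpres.ari_b_truth, 4),
                    ";".join("+".join(f) for f in cmpres.fused_groups),
                )
            )
        import pandas as pd

        comp = pd.DataFrame(
            rows,
            columns=[
                "comparison",
                "shared_bipartitions",
                "n_bipartitions_a",
                "n_bipartitions_b",
                "ari",
                "ari_a_truth",
                "ari_b_truth",
                "fused_groups",
            ],
        )
        cpath = out / "comparison.tsv"
        comp.to_csv(cpath, sep="\t", index=False)
        record_stage("compare", [cpath])
    except Exception as exc:
        raise StageError("compare", exc) from exc

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
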