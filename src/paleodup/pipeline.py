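"""Pipeline orchestration: simulate -> homology -> divergence -> synteny -> enrich.

Stages exchange plain TSV/FASTA/GFF3 files in a run directory and are
individually resumable: a stage whose outputs already exist is skipped when
``resume=True``.  A JSON manifest records the config snapshot, package
version, per-stage parameters, and SHA-256 digests of every stage output,
so two runs with the same config and seed can be compared byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .genome_io import (
    Genome,
    read_annotation_table,
    read_fasta,
    read_gff3,
    write_annotation_table,
    write_cluster_table,
    write_fasta,
    write_gff3,
)
from .homology import HomologPair, rbh_orthologs, rbh_paralogs
from .divergence import (
    DEFAULT_SYN_RATE,
    date_peak,
    detect_peaks,
    divergence_table,
)
from .synteny import (
    anchors_from_pairs,
    chain_blocks,
    classify_tandem,
    dotplot_table,
    restrict_to_blocks,
    synteny_depth,
)
from .enrichment import GroupLabel, binomial_enrich, classify_ogcs
from .synthetic_data import SimConfig, simulate

logger = logging.getLogger(__name__)

STAGES = ("simulate", "homology", "divergence", "synteny", "enrich")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _pairs_to_df(pairs: list[HomologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"a": p.a, "b": p.b, "kind": p.kind, "source": p.source} for p in pairs],
        columns=["a", "b", "kind", "source"],
    )


def _pairs_from_df(df: pd.DataFrame) -> list[HomologPair]:
    return [
        HomologPair(a=r.a, b=r.b, kind=r.kind, source=r.source)
        for r in df.itertuples()
    ]


def load_genome(outdir: Path, species: str, group: str = "default") -> Genome:
    cds = read_fasta(outdir / f"{species}.fna", nucleotide=True)
    prot = read_fasta(outdir / f"{species}.faa")
    return read_gff3(outdir / f"{species}.gff3", cds, prot, species=species, group=group)


def _species_table(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(outdir / "simulate" / "species.tsv", sep="\t")


class PipelineRunner:
    """Executes pipeline stages against one run directory."""

    def __init__(self, config: dict[str, Any], outdir: str | Path, resume: bool = False):
        self.config = config
        self.outdir = Path(outdir)
        self.resume = resume
        self.manifest: dict[str, Any] = {
            "version": __version__,
            "seed": config.get("seed", 1729),
            "config": config,
            "stages": {},
        }

    # -- helpers -----------------------------------------------------
    def _stage_dir(self, stage: str) -> Path:
        d = self.outdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _finish(self, stage: str, params: dict, t0: float, counts: dict) -> None:
        d = self.outdir / stage
        digests = {p.name: _sha256(p) for p in sorted(d.iterdir()) if p.is_file()}
        self.manifest["stages"][stage] = {
            "params": params,
            "outputs": digests,
            "counts": counts,
        }
        logger.info(
            "stage=%s wall=%.1fs %s", stage, time.time() - t0,
            " ".join(f"{k}={v}" for k, v in counts.items()),
        )

    def _done(self, stage: str, sentinel: str) -> bool:
        return self.resume and (self.outdir / stage / sentinel).exists()

    # -- stages ------------------------------------------------------
    def stage_simulate(self) -> None:
        t0 = time.time()
        d = self._stage_dir("simulate")
        params = dict(self.config.get("simulate", {}))
        if self._done("simulate", "species.tsv"):
            logger.info("stage=simulate resumed, skipping")
            return
        params.setdefault("seed", self.config.get("seed", 1729))
        import dataclasses

        known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_cfg = SimConfig(**{k: v for k, v in params.items() if k in known})
        sim_cfg.wgd_events = [tuple(e) for e in sim_cfg.wgd_events]
        genomes, annotations, truth = simulate(sim_cfg)
        rows = []
        for gm in genomes:
            write_fasta(d / f"{gm.species}.fna", {g.gene_id: g.cds for g in gm.genes()})
            write_fasta(d / f"{gm.species}.faa", {g.gene_id: g.protein for g in gm.genes()})
            write_gff3(d / f"{gm.species}.gff3", gm)
            rows.append(
                {
                    "species": gm.species,
                    "group": gm.group,
                    "split_mya": sim_cfg.speciation_times_mya.get(gm.species, 0.0),
                }
            )
        write_annotation_table(d / "go.tsv", annotations)
        write_cluster_table(d / "truth_clusters.tsv", truth.cluster_table)
        truth_rows = [
            {
                "a": sorted(k)[0],
                "b": sorted(k)[1],
                "origin": v.origin,
                "divergence": v.divergence,
            }
            for k, v in sorted(truth.pair_truth.items(), key=lambda kv: sorted(kv[0]))
        ]
        _write_tsv(
            pd.DataFrame(truth_rows, columns=["a", "b", "origin", "divergence"]),
            d / "truth_pairs.tsv",
        )
        _write_tsv(pd.DataFrame(rows), d / "species.tsv")
        self._finish(
            "simulate", params, t0,
            {"genomes": len(genomes), "truth_pairs": len(truth.pair_truth)},
        )

    def _genomes(self) -> list[Genome]:
        d = self.outdir / "simulate"
        sp = _species_table(self.outdir)
        return [load_genome(d, r.species, r.group) for r in sp.itertuples()]

    def stage_homology(self) -> None:
        t0 = time.time()
        d = self._stage_dir("homology")
        params = dict(self.config.get("homology", {}))
        genomes = self._genomes()
        focal = genomes[0]
        if self._done("homology", f"{focal.species}.paralog_pairs.tsv"):
            logger.info("stage=homology resumed, skipping")
            return
        n_pairs = 0
        paralogs = rbh_paralogs(focal)
        _write_tsv(_pairs_to_df(paralogs), d / f"{focal.species}.paralog_pairs.tsv")
        n_pairs += len(paralogs)
        for other in genomes[1:]:
            orthologs = rbh_orthologs(focal, other)
            _write_tsv(
                _pairs_to_df(orthologs),
                d / f"{focal.species}--{other.species}.ortholog_pairs.tsv",
            )
            n_pairs += len(orthologs)
        self._finish("homology", params, t0, {"pairs": n_pairs})

    def stage_divergence(self) -> None:
        t0 = time.time()
        d = self._stage_dir("divergence")
        params = dict(self.config.get("divergence", {}))
        rate = float(params.get("rate", DEFAULT_SYN_RATE))
        max_components = int(params.get("max_components", 4))
        seed = int(self.config.get("seed", 1729))
        genomes = self._genomes()
        focal = genomes[0]
        if self._done("divergence", f"{focal.species}.paralog_ks.tsv"):
            logger.info("stage=divergence resumed, skipping")
            return
        pair_files = sorted((self.outdir / "homology").glob("*.tsv"))
        n_rows = 0
        focal_table = None
        for pf in pair_files:
            pairs = _pairs_from_df(pd.read_csv(pf, sep="\t"))
            table = divergence_table(pairs, genomes)
            out = d / pf.name.replace("_pairs.tsv", "_ks.tsv")
            _write_tsv(table, out)
            n_rows += len(table)
            if pf.name == f"{focal.species}.paralog_pairs.tsv":
                focal_table = table
        peak_rows = []
        if focal_table is not None and len(focal_table) >= 30:
            peaks = detect_peaks(
                focal_table["ks"], "ks", max_components=max_components, seed=seed
            )
            for p in peaks:
                dated = date_peak(p, rate)
                peak_rows.append(
                    {
                        "statistic": p.statistic,
                        "mean": p.mean,
                        "weight": p.weight,
                        "sigma": p.sigma,
                        "label": p.label or "",
                        "time_mya": dated.time_mya,
                    }
                )
        _write_tsv(
            pd.DataFrame(
                peak_rows,
                columns=["statistic", "mean", "weight", "sigma", "label", "time_mya"],
            ),
            d / "peaks.tsv",
        )
        self._finish(
            "divergence", {**params, "rate": rate}, t0,
            {"rows": n_rows, "peaks": len(peak_rows)},
        )

    def stage_synteny(self) -> None:
        t0 = time.time()
        d = self._stage_dir("synteny")
        params = dict(self.config.get("synteny", {}))
        min_block = int(params.get("min_block", 5))
        max_gap = int(params.get("max_gap", 25))
        window = int(params.get("tandem_window", 10))
        genomes = self._genomes()
        focal = genomes[0]
        if self._done("synteny", "blocks.tsv"):
            logger.info("stage=synteny resumed, skipping")
            return
        ks_path = self.outdir / "divergence" / f"{focal.species}.paralog_ks.tsv"
        table = pd.read_csv(ks_path, sep="\t")
        pairs = [
            HomologPair(a=r.a, b=r.b, kind=r.kind) for r in table.itertuples()
        ]
        anchors = anchors_from_pairs(pairs, focal)
        blocks = chain_blocks(anchors, max_gap=max_gap, min_block=min_block)
        block_rows = [
            {
                "block_id": b.block_id,
                "chrom1": b.chrom1,
                "chrom2": b.chrom2,
                "orientation": b.orientation,
                "n_anchors": b.score,
                "anchors": ";".join(f"{a.pair.a}|{a.pair.b}" for a in b.anchors),
            }
            for b in blocks
        ]
        _write_tsv(
            pd.DataFrame(
                block_rows,
                columns=["block_id", "chrom1", "chrom2", "orientation", "n_anchors", "anchors"],
            ),
            d / "blocks.tsv",
        )
        _write_tsv(dotplot_table(anchors, blocks), d / "dotplot.tsv")
        _write_tsv(restrict_to_blocks(table, blocks), d / "block_restricted_ks.tsv")
        parts = classify_tandem(pairs, focal, window=window)
        tandem_rows = [
            {"a": p.a, "b": p.b, "class": cls}
            for cls in ("tandem", "dispersed")
            for p in parts[cls]
        ]
        _write_tsv(
            pd.DataFrame(tandem_rows, columns=["a", "b", "class"]), d / "tandem.tsv"
        )
        _, hist, modal = synteny_depth(blocks, focal, axis=1)
        _write_tsv(
            pd.DataFrame(
                [{"depth": k, "n_genes": v} for k, v in sorted(hist.items())],
                columns=["depth", "n_genes"],
            ),
            d / "depth.tsv",
        )
        self._finish(
            "synteny",
            {"min_block": min_block, "max_gap": max_gap, "tandem_window": window},
            t0,
            {"blocks": len(blocks), "anchors": len(anchors), "modal_depth": modal},
        )

    def stage_enrich(self) -> None:
        t0 = time.time()
        d = self._stage_dir("enrich")
        params = dict(self.config.get("enrichment", {}))
        alpha = float(params.get("alpha", 0.01))
        if self._done("enrich", "enrich.tsv"):
            logger.info("stage=enrich resumed, skipping")
            return
        sp = _species_table(self.outdir)
        groups = sorted(set(sp["group"]))
        if len(groups) != 2:
            logger.info("stage=enrich skipped: need exactly 2 species groups, have %d", len(groups))
            _write_tsv(pd.DataFrame(), d / "enrich.tsv")
            self._finish("enrich", params, t0, {"terms": 0})
            return
        from .genome_io import read_cluster_table

        table = read_cluster_table(
            self.outdir / "simulate" / "truth_clusters.tsv",
            species_groups=dict(zip(sp["species"], sp["group"])),
        )
        annotations = read_annotation_table(self.outdir / "simulate" / "go.tsv")
        group_a = {r.species for r in sp.itertuples() if r.group == groups[0]}
        group_b = {r.species for r in sp.itertuples() if r.group == groups[1]}
        labels = classify_ogcs(table, group_a, group_b)
        fg = sorted(c for c, l in labels.items() if l == GroupLabel.SPECIFIC_TO_A)
        bg = sorted(c for c, l in labels.items() if l == GroupLabel.SHARED)
        result = binomial_enrich(fg, bg, table, annotations, alpha=alpha)
        _write_tsv(result, d / "enrich.tsv")
        self._finish(
            "enrich", {**params, "alpha": alpha}, t0,
            {"terms": len(result), "foreground": len(fg), "background": len(bg)},
        )

    # -- driver ------------------------------------------------------
    def run(self, stages: tuple[str, ...] = STAGES) -> dict[str, Any]:
        self.outdir.mkdir(parents=True, exist_ok=True)
        for stage in stages:
            getattr(self, f"stage_{stage}")()
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True, default=str)
        return self.manifest


def run_all(config: dict[str, Any], outdir: str | Path, resume: bool = False) -> dict[str, Any]:
    """Run every stage in dependency order; returns the run manifest."""
    return PipelineRunner(config, outdir, resume=resume).run()
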