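"""End-to-end orchestration: detect -> dedup -> cluster -> name -> annotate ->
compare -> abundance -> probes, with every stage product written as a flat
TSV/FASTA/BED so external tools (a real TRF run, a real aligner) can be
interposed at any seam, and a JSON run report echoing the configuration."""
from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .catalog import catalog_stats, remove_redundant
from .comparative import (assign_chromosomes, estimate_abundance,
                          intersection_classes, match_families_across,
                          shared_by_at_least)
from .detect import detect_all
from .families import (annotate_library, assign_names, cluster_families,
                       family_diagnostics, flag_simple, score_pairs)
from .model import ArrayCatalog, DetectorParams, SelectionCriteria, TRFamily
from .probes import ProbeDesignError, design_probe, select_probe_families

STAGES = ("ingest", "detect", "dedup", "cluster", "annotate", "compare",
          "abundance", "probes")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Everything a run needs; echoed verbatim into the JSON report."""

    genome_dir: str = ""
    outdir: str = "satfam_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    detector: DetectorParams = field(default_factory=DetectorParams)
    trf_dat: dict[str, str] = field(default_factory=dict)   # assembly -> .dat path
    score_threshold: int = 200
    evalue_max: float = 1e-15
    library_fasta: str = ""
    library_coverage: float = 0.80
    chrom_maps: dict[str, str] = field(default_factory=dict)  # assembly -> TSV path
    reads_fastq: str = ""
    reads_assembly: str = ""     # which assembly's families get abundance
    abundance_k: int = 21
    abundance_min_fraction: float = 0.5
    species_prefix: str = ""
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)

    def echo(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def _family_table(families: list[TRFamily]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": f.name, "min_monomer": f.min_monomer,
        "abundance_percent": f.abundance_percent if f.abundance_percent is not None else 0.0,
        "max_array_len": f.max_array_len, "library_class": f.te_class or "",
        "library_similarity": f.te_similarity or "",
    } for f in families])


def cooccurrence_report(classes: dict[frozenset, int], path=None) -> pd.DataFrame:
    """Shared-family classes as a table: one row per assembly set (all-N
    first, then pairs), a count column, and a grand 'at least two' total."""
    rows = []
    for asms in sorted(classes, key=lambda s: (-len(s), sorted(s))):
        if len(asms) < 2:
            continue
        rows.append({"assemblies": "+".join(sorted(asms)), "n_families": classes[asms]})
    rows.append({"assemblies": "at_least_two",
                 "n_families": shared_by_at_least(classes, 2)})
    df = pd.DataFrame(rows, columns=["assemblies", "n_families"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; any prefix of the stage list is runnable.

    Returns the JSON-ready report: per-stage counts, the configuration echo,
    and wall-clock timings (timings are the only non-deterministic part).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.echo(), "stages": {}, "timings_s": {}}
    wanted = set(config.stages)

    def run_stage(name, fn):
        if name not in wanted:
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        report["timings_s"][name] = round(time.perf_counter() - t0, 3)
        return result

    # ingest ---------------------------------------------------------------
    def _ingest():
        gdir = Path(config.genome_dir)
        paths = sorted(list(gdir.glob("*.fa")) + list(gdir.glob("*.fasta")))
        if not paths:
            raise PipelineError(
                f"stage 'ingest' failed: no FASTA files in {gdir}")
        assemblies = {p.stem: io.read_fasta(p) for p in paths}
        report["stages"]["ingest"] = {
            asm: {"contigs": len(recs), "bp": sum(len(r) for r in recs)}
            for asm, recs in assemblies.items()}
        return assemblies

    assemblies = run_stage("ingest", _ingest)
    if assemblies is None:
        return report

    # detect ---------------------------------------------------------------
    def _detect():
        arrays = {}
        for asm, recs in assemblies.items():
            if asm in config.trf_dat:
                arrays[asm] = io.parse_trf_dat(config.trf_dat[asm])
            else:
                arrays[asm] = detect_all(recs, config.detector)
            io.write_arrays_tsv(arrays[asm], out / f"arrays_{asm}.tsv")
        report["stages"]["detect"] = {a: len(v) for a, v in arrays.items()}
        return arrays

    raw = run_stage("detect", _detect)
    if raw is None:
        return report

    # dedup ----------------------------------------------------------------
    def _dedup():
        catalogs = {}
        for asm, arrs in raw.items():
            cat = remove_redundant(arrs, assembly_id=asm,
                                   provenance={"detector": asdict(config.detector)})
            io.write_arrays_tsv(cat.arrays, out / f"fields_{asm}.tsv")
            io.write_bed(cat.arrays, out / f"fields_{asm}.bed")
            catalogs[asm] = cat
        report["stages"]["dedup"] = {a: catalog_stats(c) for a, c in catalogs.items()}
        return catalogs

    catalogs = run_stage("dedup", _dedup)
    if catalogs is None:
        return report

    # cluster + name -------------------------------------------------------
    def _cluster():
        fam_sets = {}
        for asm, cat in catalogs.items():
            matches = score_pairs(cat, evalue_max=config.evalue_max)
            fams = cluster_families(cat, matches, config.score_threshold)
            assign_names(fams, species_prefix=config.species_prefix, assembly_id=asm)
            cmap = (io.read_chrom_map(config.chrom_maps[asm])
                    if asm in config.chrom_maps else None)
            for f in fams:
                assign_chromosomes(f, cmap)
            fam_sets[asm] = fams
        report["stages"]["cluster"] = {a: len(v) for a, v in fam_sets.items()}
        return fam_sets

    fam_sets = run_stage("cluster", _cluster)
    if fam_sets is None:
        return report

    # annotate -------------------------------------------------------------
    def _annotate():
        if not config.library_fasta:
            return {"skipped": "no repeat library configured"}
        library = io.read_fasta(config.library_fasta)
        n_te = {}
        for asm, fams in fam_sets.items():
            for f in fams:
                annotate_library(f, catalogs[asm], library,
                                 coverage_threshold=config.library_coverage)
            n_te[asm] = sum(f.is_te for f in fams)
        return {"te_families": n_te}

    ann = run_stage("annotate", _annotate)
    if "annotate" in wanted:
        report["stages"]["annotate"] = ann
    for asm, fams in fam_sets.items():
        io.write_families_tsv(fams, out / f"families_{asm}.tsv", assembly_id=asm)
        diag = family_diagnostics(fams, catalogs[asm])
        pd.DataFrame(diag).to_csv(out / f"diagnostics_{asm}.tsv", sep="\t", index=False)

    # compare --------------------------------------------------------------
    def _compare():
        if len(fam_sets) < 2:
            return {"skipped": "fewer than two assemblies"}
        linked = match_families_across(fam_sets, config.score_threshold)
        classes = intersection_classes(linked)
        cooccurrence_report(classes, out / "cooccurrence.tsv")
        return {"classes": {"+".join(sorted(k)): v for k, v in classes.items()},
                "at_least_two": shared_by_at_least(classes, 2),
                "_linked": linked, "_classes": classes}

    cmp_result = run_stage("compare", _compare)
    if cmp_result is not None:
        report["stages"]["compare"] = {k: v for k, v in cmp_result.items()
                                       if not k.startswith("_")}

    # abundance ------------------------------------------------------------
    def _abundance():
        if not config.reads_fastq:
            return {"skipped": "no reads configured"}
        reads = io.read_fastq(config.reads_fastq)
        asm = config.reads_assembly or sorted(fam_sets)[0]
        by_id = {a.id: a for a in catalogs[asm].arrays}
        rows = []
        for f in fam_sets[asm]:
            seqs = [by_id[m].array_sequence for m in f.members if m in by_id]
            est = estimate_abundance(f, seqs, reads,
                                     min_kmer_fraction=config.abundance_min_fraction,
                                     k=config.abundance_k)
            f.abundance_percent = est.percent
            rows.append({"family": f.name, "reads_aligned": est.reads_aligned,
                         "reads_total": est.reads_total,
                         "percent": round(est.percent, 4)})
        pd.DataFrame(rows).to_csv(out / f"abundance_{asm}.tsv", sep="\t", index=False)
        io.write_families_tsv(fam_sets[asm], out / f"families_{asm}.tsv", assembly_id=asm)
        return {"assembly": asm, "families": len(rows)}

    ab = run_stage("abundance", _abundance)
    if ab is not None:
        report["stages"]["abundance"] = ab

    # probes ---------------------------------------------------------------
    def _probes():
        asm = config.reads_assembly or sorted(fam_sets)[0]
        fams = fam_sets[asm]
        n_assemblies = {f.name: 1 for f in fams}
        if cmp_result is not None and "_classes" in cmp_result:
            linked = cmp_result["_linked"]
            nodes = {(a, f.name) for a, fl in linked.sets.items() for f in fl}
            from .families import _UnionFind
            uf = _UnionFind(sorted(nodes))
            for x, y, _ in linked.links:
                uf.union(x, y)
            groups: dict[tuple, set[str]] = {}
            for node in nodes:
                groups.setdefault(uf.find(node), set()).add(node[0])
            for f in fams:
                n_assemblies[f.name] = len(groups.get(uf.find((asm, f.name)), {asm}))
        table = _family_table(fams)
        selected = select_probe_families(table, n_assemblies, config.selection)
        chosen_names = list(selected["name"])
        by_name = {f.name: f for f in fams}
        chosen = [by_name[n] for n in chosen_names
                  if not flag_simple(by_name[n], config.selection.min_monomer)]
        probes = []
        failures = {}
        for f in chosen:
            try:
                probes.append(design_probe(f, catalogs[asm], fams))
            except ProbeDesignError as exc:
                failures[f.name] = str(exc)
        io.write_probes_tsv(probes, out / "probes.tsv")
        if probes:
            io.write_probes_fasta(probes, out / "probes.fasta")
        return {"assembly": asm, "selected": [f.name for f in chosen],
                "designed": len(probes), "failures": failures}

    pr = run_stage("probes", _probes)
    if pr is not None:
        report["stages"]["probes"] = pr

    io.write_json_report({k: v for k, v in report.items() if k != "timings_s"},
                         out / "report.json")
    return report
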