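"""End-to-end orchestration, strain-collection summaries, and run reports.

The pipeline wires the stages together: ANI matrix and genomospecies calls
from genome FASTAs, triple-algorithm pan-genome and compartments from protein
FASTAs, discovery-curve fits, the ANI dendrogram, and 16S screening verdicts.
It also implements the strain-collection bookkeeping: merging genome-confirmed
and screening-confirmed strain lists and summarizing isolation sources as
counts with rounded percentages (half-up, printed with their numerator and
denominator).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import anib, curves, pangenome, phylo, signature
from .genome_io import read_assembly, read_proteome, read_fasta


@dataclass
class PipelineConfig:
    """Paths and parameters of one end-to-end run."""

    output_dir: str
    genome_fastas: list[str] = field(default_factory=list)
    proteome_fastas: list[str] = field(default_factory=list)
    ssu_fasta: str | None = None
    ssu_reference: str | None = None
    signature_profile: str | None = None
    reference_genome: str | None = None  # BDBH reference; default first proteome
    anib_params: anib.AnibParams = field(default_factory=anib.AnibParams)
    similarity: pangenome.SimilarityThresholds = field(
        default_factory=pangenome.SimilarityThresholds)
    screening: signature.ScreeningThresholds = field(
        default_factory=signature.ScreeningThresholds)
    n_permutations: int = 100
    seed: int = 1
    run_curves: bool = True
    run_dendrogram: bool = True

    def validate(self) -> None:
        for path in [*self.genome_fastas, *self.proteome_fastas,
                     self.ssu_fasta, self.ssu_reference, self.signature_profile]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(path)
        if (self.ssu_fasta is None) != (self.ssu_reference is None):
            raise ValueError("16S screening needs both a panel and a reference")

    def config_hash(self) -> str:
        def default(o):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)
        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    artifacts: dict[str, str] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    status: str = "complete"


def run_full_analysis(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Deterministic stages reproduce byte-identically on rerun; stochastic
    stages (curve sampling) are reproducible given the configured seed.
    Outputs land under ``config.output_dir``; the report lists every artifact.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config.config_hash(), config.seed)

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
            def __exit__(self, *exc):
                report.timings[name] = time.perf_counter() - self.t0
        return _Timer()

    try:
        if len(config.genome_fastas) >= 2:
            with stage("anib"):
                assemblies = [read_assembly(p) for p in config.genome_fastas]
                matrix = anib.build_ani_matrix(assemblies, config.anib_params)
                anib.write_ani_tables(matrix, out / "ani_pairs.tsv",
                                      out / "ani_matrix.tsv")
                clusters = anib.cluster_genomospecies(
                    matrix, config.anib_params.species_threshold_pct)
                (out / "genomospecies.tsv").write_text(
                    "cluster\tgenomes\n" + "\n".join(
                        f"{k}\t{','.join(sorted(c))}" for k, c in enumerate(clusters)) + "\n")
                report.artifacts["ani_matrix"] = str(out / "ani_matrix.tsv")
                report.artifacts["genomospecies"] = str(out / "genomospecies.tsv")
                if config.run_dendrogram and len(assemblies) >= 3:
                    tree = anib.ani_dendrogram(matrix)
                    phylo.write_newick(tree, out / "ani_dendrogram.nwk")
                    report.artifacts["ani_dendrogram"] = str(out / "ani_dendrogram.nwk")

        if len(config.proteome_fastas) >= 2:
            with stage("pangenome"):
                proteomes = [read_proteome(p) for p in config.proteome_fastas]
                hits = pangenome.all_vs_all_hits(proteomes, config.similarity)
                ref = config.reference_genome or proteomes[0].genome_id
                bdbh = pangenome.bdbh_cluster(hits, proteomes, ref)
                cogt = pangenome.cog_triangles_cluster(hits)
                omcl = pangenome.omcl_cluster(hits)
                genomes = [p.genome_id for p in proteomes]
                pan = pangenome.pangenome_intersection(cogt, omcl)
                matrix = pangenome.compartmentalize(pan, genomes)
                matrix.to_frame().to_csv(out / "pangenome_matrix.tsv", sep="\t")
                core = pangenome.consensus_core(bdbh, cogt, omcl, genomes)
                (out / "consensus_core.txt").write_text(
                    "\n".join(c.cluster_id for c in core) + "\n")
                report.artifacts["pangenome_matrix"] = str(out / "pangenome_matrix.tsv")
                report.artifacts["consensus_core"] = str(out / "consensus_core.txt")

                if config.run_curves and len(genomes) >= 3:
                    with stage("curves"):
                        curve = curves.sample_gene_discovery(
                            matrix, config.n_permutations, config.seed)
                        fits = {
                            "core_tettelin": asdict(curves.fit_core(curve, "tettelin")),
                            "core_willenbrock": asdict(curves.fit_core(curve, "willenbrock")),
                            "pan_tettelin": asdict(curves.fit_pan(curve)),
                        }
                        (out / "curve_fits.json").write_text(json.dumps(fits, indent=2))
                        curves.curve_table(curve).to_csv(
                            out / "discovery_curves.tsv", sep="\t", index=False)
                        report.artifacts["curve_fits"] = str(out / "curve_fits.json")

        if config.ssu_fasta is not None:
            with stage("screening"):
                panel = read_fasta(config.ssu_fasta, "nucleotide")
                reference = read_fasta(config.ssu_reference, "nucleotide")[0]
                profile = signature.read_profile(config.signature_profile)
                verdicts = [signature.screen_sequence(q, reference, profile,
                                                      config.screening)
                            for q in panel]
                signature.verdicts_table(verdicts).to_csv(
                    out / "screening_verdicts.tsv", sep="\t", index=False)
                report.artifacts["screening"] = str(out / "screening_verdicts.tsv")
    except Exception:
        report.status = "partial"
        raise
    finally:
        manifest = {"config_hash": report.config_hash, "seed": report.seed,
                    "status": report.status, "artifacts": report.artifacts,
                    "timings": report.timings}
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


# ---------------------------------------------------------------------------
# strain-collection bookkeeping


def merge_strain_evidence(genome_confirmed: pd.DataFrame,
                          screening_confirmed: pd.DataFrame) -> pd.DataFrame:
    """Union of the two evidence routes, one row per strain.

    Both inputs are strain-metadata frames (columns strain_id, label,
    source_tags, geography). A strain confirmed by both routes appears once
    with evidence "genome+screening"; conflicting metadata for one id is an
    error listing the conflicts.
    """
    for df in (genome_confirmed, screening_confirmed):
        if df["strain_id"].duplicated().any():
            raise ValueError("duplicate strain ids within one evidence list")
    g = genome_confirmed.copy()
    s = screening_confirmed.copy()
    g["evidence"] = "genome"
    s["evidence"] = "screening"
    overlap = set(g["strain_id"]) & set(s["strain_id"])
    conflicts = []
    for sid in sorted(overlap):
        rg = g[g["strain_id"] == sid].iloc[0]
        rs = s[s["strain_id"] == sid].iloc[0]
        for col in ("label", "source_tags", "geography"):
            if rg[col] != rs[col]:
                conflicts.append((sid, col, rg[col], rs[col]))
    if conflicts:
        raise ValueError(f"conflicting metadata for merged strains: {conflicts}")
    merged = pd.concat([g, s[~s["strain_id"].isin(overlap)]], ignore_index=True)
    merged.loc[merged["strain_id"].isin(overlap), "evidence"] = "genome+screening"
    return merged.sort_values("strain_id").reset_index(drop=True)


def _round_half_up(x: float) -> int:
    import math
    return int(math.floor(x + 0.5))


def summarize_strain_sources(table: pd.DataFrame,
                             conditionals: list[tuple[str, str]] = ()
                             ) -> pd.DataFrame:
    """Counts and rounded percentages per source tag.

    The denominator is the number of strains with any source information;
    percentages are rounded half-up to the nearest integer and always
    reported with their numerator and denominator (tags may overlap, so
    percentages need not sum to 100). ``conditionals`` requests additional
    rows computed within a parent tag, e.g. ("marine", "aquatic") for the
    share of marine strains among aquatic ones.
    """
    if table.empty:
        raise ValueError("empty strain table")
    tags_per_strain = table["source_tags"]
    with_info = tags_per_strain.map(bool)
    denominator = int(with_info.sum())
    all_tags = sorted({t for tags in tags_per_strain for t in tags})
    rows = []
    for tag in all_tags:
        count = int(tags_per_strain.map(lambda s: tag in s).sum())
        rows.append({"tag": tag, "parent": "", "count": count,
                     "denominator": denominator,
                     "percent": _round_half_up(100.0 * count / denominator)})
    for child, parent in conditionals:
        if parent not in all_tags:
            raise ValueError(f"unknown parent tag {parent!r} in conditional request")
        parent_rows = tags_per_strain.map(lambda s: parent in s)
        denom = int(parent_rows.sum())
        count = int((tags_per_strain.map(lambda s: child in s) & parent_rows).sum())
        rows.append({"tag": child, "parent": parent, "count": count,
                     "denominator": denom,
                     "percent": _round_half_up(100.0 * count / denom) if denom else 0})
    return pd.DataFrame(rows)


def strain_table_from_counts(n_total: int, n_with_source: int,
                             tag_counts: dict[str, int],
                             nested: dict[str, tuple[str, int]] = {},
                             ) -> pd.DataFrame:
    """Synthetic strain table realizing the given marginal tag counts.

    Builds ``n_total`` placeholder strains of which ``n_with_source`` carry
    source tags; each tag is assigned to its first ``count`` strains (tags
    overlap freely, as real strains are assigned to one or more
    environments). ``nested`` constrains a child tag to the first ``count``
    strains of its parent tag, e.g. {"marine": ("aquatic", 49)}. Strain
    identities are synthetic; only the marginal counts are meaningful.
    """
    for tag, count in tag_counts.items():
        if count > n_with_source:
            raise ValueError(f"tag {tag!r} count exceeds strains with source info")
    rows = []
    for i in range(n_total):
        tags: set[str] = set()
        if i < n_with_source:
            for tag, count in tag_counts.items():
                if i < count:
                    tags.add(tag)
            for child, (parent, count) in nested.items():
                if parent not in tag_counts:
                    raise ValueError(f"nested tag {child!r} has unknown parent {parent!r}")
                if i < min(count, tag_counts[parent]):
                    tags.add(child)
            if not tags:
                # source information exists but matches none of the named
                # tags; keeps the denominator equal to n_with_source
                tags.add("other")
        rows.append({"strain_id": f"strain_{i:03d}", "label": "",
                     "source_tags": tags, "geography": ""})
    return pd.DataFrame(rows)
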