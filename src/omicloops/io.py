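"""Readers and writers for the cohort's table dialects.

The canonical interchange format is TSV with a one-line header and sample
identifiers in the first column. A minimal site-level VCF (GT only) bridge is
provided for genotypes. Association edge lists round-trip through a stable,
diffable TSV (sorted by p then node ids). A JSON run manifest records the
configuration hash, seed and every output file.

Readers align tables on a sample roster — the intersection of the genotype
and phenotype sample ids — and report per-omic sample counts and dropped
identifiers; samples are never imputed, only intersected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .associations import AssociationEdge
from .tables import GenotypeTable, MetaboliteTable, MicrobiomeCounts, PhenotypeSeries

__all__ = [
    "write_cohort",
    "read_tables",
    "LoadReport",
    "write_edges",
    "read_edges",
    "write_vcf",
    "read_vcf",
    "write_manifest",
]

EDGE_COLUMNS = [
    "node_a", "type_a", "node_b", "type_b", "age", "beta", "p", "q", "sign",
    "se", "stage", "tier", "n_used",
]


def _write_tsv(df: pd.DataFrame, path, index_label="sample_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def _read_tsv(path, index_col=0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate sample ids in {path}: {dups}")
    return df


def write_cohort(cohort, outdir) -> dict:
    """Write a cohort's tables as TSV; returns {name: path} of files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    _write_tsv(cohort.genotype.mac, outdir / "genotype.tsv")
    files["genotype"] = outdir / "genotype.tsv"
    cohort.genotype.annotations.to_csv(
        outdir / "genotype_annotations.tsv", sep="\t", index_label="snp_id"
    )
    files["genotype_annotations"] = outdir / "genotype_annotations.tsv"

    for age, mb in sorted(cohort.microbiome.items()):
        p = outdir / f"microbiome_age{age:g}.tsv"
        _write_tsv(mb.counts, p)
        files[f"microbiome_age{age:g}"] = p

    _write_tsv(cohort.metabolome.abundance, outdir / "metabolome.tsv")
    files["metabolome"] = outdir / "metabolome.tsv"
    cohort.metabolome.pathway_map.to_csv(
        outdir / "metabolite_pathways.tsv", sep="\t", index_label="metabolite_id"
    )
    files["metabolite_pathways"] = outdir / "metabolite_pathways.tsv"

    ph = cohort.phenotypes
    _write_tsv(ph.bmi_percentile, outdir / "bmi_percentile.tsv")
    _write_tsv(ph.bmi_category, outdir / "bmi_category.tsv")
    _write_tsv(ph.covariates, outdir / "covariates.tsv")
    files["bmi_percentile"] = outdir / "bmi_percentile.tsv"
    files["bmi_category"] = outdir / "bmi_category.tsv"
    files["covariates"] = outdir / "covariates.tsv"
    return files


@dataclass
class LoadReport:
    """Per-omic sample accounting from a read_tables call."""

    roster_size: int
    per_omic_n: dict = field(default_factory=dict)
    dropped: dict = field(default_factory=dict)

    def __str__(self) -> str:
        lines = [f"sample roster: {self.roster_size}"]
        for k in sorted(self.per_omic_n):
            d = len(self.dropped.get(k, []))
            lines.append(f"  {k}: {self.per_omic_n[k]} samples ({d} dropped)")
        return "\n".join(lines)


def read_tables(indir, allowed_levels: dict | None = None):
    """Read a cohort directory back into aligned table objects.

    The roster is the intersection of genotype and phenotype sample ids;
    microbiome and metabolome tables are restricted to roster members.
    Returns ``(genotype, microbiome_by_age, metabolome, phenotypes, report)``.
    """
    indir = Path(indir)
    for required in ("genotype.tsv", "bmi_percentile.tsv", "covariates.tsv"):
        if not (indir / required).exists():
            raise FileNotFoundError(f"missing input file: {indir / required}")

    mac = _read_tsv(indir / "genotype.tsv")
    ann = _read_tsv(indir / "genotype_annotations.tsv")
    pct = _read_tsv(indir / "bmi_percentile.tsv")
    cat = _read_tsv(indir / "bmi_category.tsv")
    cov = _read_tsv(indir / "covariates.tsv")
    pct.columns = [float(c) for c in pct.columns]
    cat.columns = [float(c) for c in cat.columns]

    roster = mac.index.intersection(pct.index)
    report = LoadReport(roster_size=len(roster))
    report.per_omic_n["genotype"] = len(roster)
    report.dropped["genotype"] = sorted(set(mac.index) - set(roster))
    report.per_omic_n["phenotypes"] = len(roster)
    report.dropped["phenotypes"] = sorted(set(pct.index) - set(roster))

    genotype = GenotypeTable(mac.loc[roster], ann)
    phenotypes = PhenotypeSeries(
        bmi_percentile=pct.loc[roster],
        bmi_category=cat.loc[roster],
        covariates=cov.loc[roster],
        allowed_levels=allowed_levels or {},
    )

    microbiome = {}
    for p in sorted(indir.glob("microbiome_age*.tsv")):
        age = float(p.stem.replace("microbiome_age", ""))
        counts = _read_tsv(p)
        vals = counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError(f"non-integer microbiome counts in {p}")
        keep = counts.index.intersection(roster)
        report.per_omic_n[f"microbiome_age{age:g}"] = len(keep)
        report.dropped[f"microbiome_age{age:g}"] = sorted(set(counts.index) - set(keep))
        microbiome[age] = MicrobiomeCounts(counts.loc[keep], age_years=age)

    metabolome = None
    if (indir / "metabolome.tsv").exists():
        ab = _read_tsv(indir / "metabolome.tsv")
        pmap = _read_tsv(indir / "metabolite_pathways.tsv")
        keep = ab.index.intersection(roster)
        report.per_omic_n["metabolome"] = len(keep)
        report.dropped["metabolome"] = sorted(set(ab.index) - set(keep))
        metabolome = MetaboliteTable(ab.loc[keep], pmap)

    return genotype, microbiome, metabolome, phenotypes, report


def _age_to_str(age) -> str:
    if age is None:
        return ""
    if isinstance(age, tuple):
        return f"{age[0]:g}-{age[1]:g}"
    return f"{float(age):g}"


def _age_from_str(s):
    if s is None or (isinstance(s, float) and np.isnan(s)) or s == "":
        return None
    s = str(s)
    if "-" in s:  # persistence-run age range "lo-hi" (ages are non-negative)
        lo, hi = s.split("-", 1)
        return (float(lo), float(hi))
    return float(s)


def write_edges(edges, path) -> None:
    """Write an edge list as stable TSV (sorted by p, then node ids)."""
    rows = []
    for e in sorted(edges, key=lambda e: (e.p, e.node_a, e.node_b)):
        rows.append(
            {
                "node_a": e.node_a, "type_a": e.type_a,
                "node_b": e.node_b, "type_b": e.type_b,
                "age": _age_to_str(e.age),
                "beta": np.format_float_scientific(e.beta, precision=16),
                "p": np.format_float_scientific(e.p, precision=16),
                "q": "" if e.q is None else np.format_float_scientific(e.q, precision=16),
                "sign": e.sign,
                "se": np.format_float_scientific(e.se, precision=16),
                "stage": e.stage,
                "tier": e.tier or "",
                "n_used": "" if e.n_used is None else e.n_used,
            }
        )
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_edges(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"age": str, "tier": str})
    edges = []
    for _, r in df.iterrows():
        q = r.get("q")
        tier = r.get("tier")
        n_used = r.get("n_used")
        edges.append(
            AssociationEdge(
                node_a=r["node_a"], type_a=r["type_a"],
                node_b=r["node_b"], type_b=r["type_b"],
                age=_age_from_str(r["age"]),
                beta=float(r["beta"]), se=float(r["se"]), p=float(r["p"]),
                sign=int(r["sign"]), stage=r["stage"],
                q=None if pd.isna(q) else float(q),
                tier=None if (pd.isna(tier) or tier == "") else str(tier),
                n_used=None if pd.isna(n_used) else int(n_used),
            )
        )
    return edges


def write_vcf(genotype: GenotypeTable, path) -> None:
    """Export genotypes as a minimal site-level VCF (GT field only).

    Alleles are placeholders (REF=A, ALT=G); the ALT allele encodes the minor
    allele, so GT dosage of ALT equals the MAC. The gene symbol is kept in
    INFO as GENE=.
    """
    samples = genotype.sample_ids
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        ann = genotype.annotations
        order = sorted(
            genotype.snp_ids,
            key=lambda s: (str(ann.loc[s, "chrom"]), int(ann.loc[s, "position"])),
        )
        for snp in order:
            row = genotype.mac[snp]
            gts = [gt_map.get(float(v), "./.") if np.isfinite(v) else "./." for v in row]
            fh.write(
                f"{ann.loc[snp, 'chrom']}\t{int(ann.loc[snp, 'position'])}\t{snp}"
                f"\tA\tG\t.\t.\tGENE={ann.loc[snp, 'gene']}\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeTable:
    """Import a GT-only VCF as minor-allele counts.

    The ALT allele is treated as the minor allele only when its sample
    frequency is <= 0.5; otherwise the dosage is complemented so the table
    always stores counts of the rarer allele.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    macs: dict[str, np.ndarray] = {}
    ann_rows = []
    for rec in vf:
        dosage = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None or any(a is None for a in gt):
                continue
            dosage[i] = float(sum(1 for a in gt if a == 1))
        finite = dosage[np.isfinite(dosage)]
        if finite.size and finite.mean() / 2.0 > 0.5:
            dosage = 2.0 - dosage
        snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
        macs[snp_id] = dosage
        try:
            gene = rec.info.get("GENE", "")
        except (KeyError, ValueError):  # GENE absent from the header
            gene = ""
        ann_rows.append(
            {"snp_id": snp_id, "chrom": str(rec.chrom), "position": int(rec.pos),
             "gene": gene}
        )
    mac = pd.DataFrame(macs, index=samples)
    ann = pd.DataFrame(ann_rows).set_index("snp_id")
    return GenotypeTable(mac, ann)


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config_obj, seed, outputs: dict, counts: dict | None = None) -> None:
    manifest = {
        "config_hash": config_hash(config_obj),
        "seed": int(seed),
        "outputs": {k: str(Path(v).name) for k, v in sorted(outputs.items())},
        "stage_counts": dict(sorted((counts or {}).items())),
    }
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
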