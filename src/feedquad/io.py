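"""Plain-text readers and writers for the pipeline's interchange formats.

Everything on disk is TSV, BED (0-based half-open) or GFF3 (1-based closed, converted
to half-open at this boundary). Floats are written with a fixed format so reruns with
the same seed are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.6g"


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def read_tsv(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    """Long-format phenotype table: one row per weigh day per animal."""
    rows = []
    for rec in pheno.itertuples(index=False):
        for day, kg in rec.weights:
            row = {
                "animal_id": rec.animal_id,
                "day": int(day),
                "weight_kg": kg,
                "intake_total": rec.intake_total,
                "excluded": int(rec.excluded),
            }
            for breed, frac in sorted(rec.breed_fractions.items()):
                row[f"breed_{breed}"] = frac
            rows.append(row)
    write_tsv(pd.DataFrame(rows).fillna(0.0), path)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Inverse of :func:`write_phenotypes`: one row per animal with a weights list."""
    long = read_tsv(path)
    breed_cols = [c for c in long.columns if c.startswith("breed_")]
    out = []
    for animal, sub in long.groupby("animal_id", sort=True):
        first = sub.iloc[0]
        fracs = {
            c.removeprefix("breed_"): float(first[c])
            for c in breed_cols
            if float(first[c]) > 0
        }
        out.append(
            {
                "animal_id": animal,
                "weights": list(zip(sub["day"].tolist(), sub["weight_kg"].tolist())),
                "intake_total": float(first["intake_total"]),
                "breed_fractions": fracs,
                "excluded": bool(first["excluded"]),
            }
        )
    return pd.DataFrame(out)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index=True, index_label=index_label, float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_calls_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """CNV calls as BED: chrom, start, end, name=sample, score=round(1000*posterior), cn."""
    bed = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "start": calls["start"],
            "end": calls["end"],
            "name": calls["sample"],
            "score": (1000 * calls["score"].astype(float)).round().astype(int)
            if len(calls)
            else pd.Series(dtype=int),
            "cn": calls["cn"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_calls_bed(path: str | Path) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "name", "score", "cn"]
    )
    return pd.DataFrame(
        {
            "sample": bed["name"],
            "chrom": bed["chrom"].astype(str),
            "start": bed["start"],
            "end": bed["end"],
            "cn": bed["cn"],
            "score": bed["score"] / 1000.0,
        }
    )


def write_bed3(df: pd.DataFrame, path: str | Path, extra: list[str] | None = None) -> None:
    cols = ["chrom", "start", "end"] + (extra or [])
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    """Gene annotation as GFF3 (converting half-open to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.itertuples(index=False):
            fh.write(
                f"{r.chrom}\tfeedquad\tgene\t{int(r.start) + 1}\t{int(r.end)}\t.\t.\t.\t"
                f"ID={r.gene};Name={r.gene}\n"
            )


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Load gene spans from GFF3 or BED into half-open (chrom, start, end, gene)."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] not in {"gene", "mRNA"}:
                    continue
                attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
                gene = attrs.get("Name") or attrs.get("ID") or f"{f[0]}:{f[3]}"
                rows.append(
                    {"chrom": f[0], "start": int(f[3]) - 1, "end": int(f[4]), "gene": gene}
                )
        return pd.DataFrame(rows)
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4]
    bed.columns = ["chrom", "start", "end", "gene"]
    bed["chrom"] = bed["chrom"].astype(str)
    return bed


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path: str | Path) -> list[str]:
    return [g for g in Path(path).read_text().splitlines() if g.strip()]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
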