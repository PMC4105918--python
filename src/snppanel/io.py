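"""Readers and writers for the interchange formats the pipeline touches:
genepop genotype files, wide genotype TSV, environment TSV and Newick trees.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np
import pandas as pd

from .datatypes import (
    GEO_COLUMNS,
    MISSING,
    MONTHLY_COLUMNS,
    EnvironmentTable,
    GenotypeDataset,
)

# ---------------------------------------------------------------------------
# genepop


def _split_alleles(code: str, locus: str, lineno: int) -> tuple[str, str]:
    if len(code) == 4:
        return code[:2], code[2:]
    if len(code) == 6:
        return code[:3], code[3:]
    raise ValueError(
        f"line {lineno}: genotype {code!r} at locus {locus!r} is neither "
        "4- nor 6-digit"
    )


def read_genepop(path) -> GenotypeDataset:
    """Read a genepop file into a :class:`GenotypeDataset`.

    The panel-wide minor allele at each locus is the allele with the lower
    overall frequency (ties broken by the smaller allele code); calls count
    that allele.  ``0000``/``000000`` is missing.  Accepts 2- or 3-digit
    allele codes and ``POP``/``Pop``/``pop`` separators; locus names one
    per line or comma-separated.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty genepop file")
    # title line, then locus names until the first POP separator
    locus_ids: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [t.strip() for t in lines[i].split(",") if t.strip()]
        locus_ids.extend(chunk)
        i += 1
    if i == len(lines):
        raise ValueError("no POP separator found")
    if len(set(locus_ids)) != len(locus_ids):
        raise ValueError("duplicate locus names in genepop header")

    individual_ids: list[str] = []
    population_labels: list[str] = []
    rows: list[list[str]] = []  # raw per-allele-pair codes
    pop_index = 0
    pop_first_id: str | None = None
    for lineno, raw in enumerate(lines[i:], start=i + 1):
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_index += 1
            pop_first_id = None
            continue
        if "," not in line:
            raise ValueError(f"line {lineno}: expected 'id , genotypes'")
        ind_id, _, geno = line.partition(",")
        ind_id = ind_id.strip()
        codes = geno.split()
        if len(codes) != len(locus_ids):
            raise ValueError(
                f"line {lineno}: {len(codes)} genotypes for "
                f"{len(locus_ids)} loci"
            )
        if pop_first_id is None:
            pop_first_id = ind_id or f"pop{pop_index}"
        individual_ids.append(ind_id)
        # genepop convention: populations are commonly named after their
        # first (or last) member; we use the first member's id.
        population_labels.append(pop_first_id)
        rows.append(codes)

    if not rows:
        raise ValueError("genepop file contains no individuals")

    n, m = len(rows), len(locus_ids)
    # per-locus allele bookkeeping
    allele_counts: list[dict[str, int]] = [dict() for _ in range(m)]
    pairs = np.empty((n, m, 2), dtype=object)
    for r, codes in enumerate(rows):
        for j, code in enumerate(codes):
            a1, a2 = _split_alleles(code, locus_ids[j], 0)
            pairs[r, j, 0], pairs[r, j, 1] = a1, a2
            zero = "0" * len(a1)
            for a in (a1, a2):
                if a != zero:
                    allele_counts[j][a] = allele_counts[j].get(a, 0) + 1

    calls = np.full((n, m), MISSING, dtype=np.int8)
    minor_alleles: dict[str, tuple[str, str]] = {}
    for j, counts in enumerate(allele_counts):
        alleles = sorted(counts)
        if len(alleles) > 2:
            raise ValueError(
                f"locus {locus_ids[j]!r} not biallelic: alleles {alleles}"
            )
        if not alleles:
            minor_alleles[locus_ids[j]] = ("", "")
            continue
        if len(alleles) == 1:
            minor, major = alleles[0], alleles[0]
        else:
            a, b = alleles  # a < b lexicographically
            # lower overall frequency wins; tie -> smaller allele code
            minor, major = (a, b) if counts[a] <= counts[b] else (b, a)
        minor_alleles[locus_ids[j]] = (minor, major)
        zero = "0" * len(minor)
        for r in range(n):
            a1, a2 = pairs[r, j]
            if a1 == zero or a2 == zero:
                continue
            calls[r, j] = int(a1 == minor) + int(a2 == minor)

    return GenotypeDataset(
        individual_ids=individual_ids,
        population_labels=population_labels,
        locus_ids=locus_ids,
        calls=calls,
        metadata={"minor_alleles": minor_alleles, "source": str(path)},
    )


def write_genepop(dataset: GenotypeDataset, path, title: str = "snppanel export") -> None:
    """Write a dataset in genepop 2-digit format.

    The counted (panel-minor) allele is written as code ``01`` and the
    other as ``02``; re-reading reproduces the calls matrix whenever the
    counted allele's overall frequency is at most 0.5, which holds for any
    dataset oriented at load or simulation time.
    """
    code = {0: "0202", 1: "0102", 2: "0101", MISSING: "0000"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in dataset.locus_ids:
            fh.write(locus + "\n")
        for pop, idx in dataset.population_indices().items():
            fh.write("POP\n")
            for i in idx:
                genos = " ".join(code[int(c)] for c in dataset.calls[i])
                fh.write(f"{dataset.individual_ids[i]} , {genos}\n")


# ---------------------------------------------------------------------------
# wide genotype TSV


def read_genotype_table(path) -> GenotypeDataset:
    """Read a wide TSV: individual, population, then one column per locus
    with cells in {0, 1, 2, NA}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("individual", "population"):
        if col not in df.columns:
            raise ValueError(f"genotype table missing column {col!r}")
    locus_ids = [c for c in df.columns if c not in ("individual", "population")]
    calls = np.full((len(df), len(locus_ids)), MISSING, dtype=np.int8)
    for j, locus in enumerate(locus_ids):
        for i, cell in enumerate(df[locus]):
            if pd.isna(cell) or cell == "NA":
                continue
            if cell not in ("0", "1", "2"):
                raise ValueError(
                    f"row {i + 2}, column {locus!r}: cell {cell!r} outside "
                    "{0,1,2,NA}"
                )
            calls[i, j] = int(cell)
    return GenotypeDataset(
        individual_ids=df["individual"].tolist(),
        population_labels=df["population"].tolist(),
        locus_ids=locus_ids,
        calls=calls,
        metadata={"source": str(path)},
    )


def write_genotype_table(dataset: GenotypeDataset, path) -> None:
    df = dataset.to_frame().astype(object)
    for locus in dataset.locus_ids:
        df[locus] = df[locus].map(lambda c: "NA" if c == MISSING else str(int(c)))
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# environment TSV


def read_environment_table(path, genotype_dataset: GenotypeDataset | None = None) -> EnvironmentTable:
    """Read and validate the per-population environment TSV.

    If a genotype dataset is supplied, a population-set mismatch is
    reported as a warning listing the symmetric difference (extra
    environment rows are allowed; the genotype side decides the analysis
    population set).
    """
    df = pd.read_csv(path, sep="\t")
    env = EnvironmentTable(df)
    if genotype_dataset is not None:
        geno = set(genotype_dataset.populations)
        envp = set(env.populations)
        if geno != envp:
            diff = sorted(geno.symmetric_difference(envp))
            warnings.warn(
                f"population sets differ between genotypes and environment "
                f"table; symmetric difference: {diff}",
                stacklevel=2,
            )
    return env


def write_environment_table(env: EnvironmentTable, path) -> None:
    cols = ["population"] + GEO_COLUMNS + MONTHLY_COLUMNS
    extra = [c for c in env.table.columns if c not in cols]
    env.table[cols + extra].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick


def write_newick(tree: dendropy.Tree, path) -> None:
    """Write a tree as Newick with bootstrap supports as internal-node
    labels and branch lengths at 6 significant digits."""
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
        unquoted_underscores=True,
    )
    with open(path, "w") as fh:
        fh.write(s if s.endswith("\n") else s + "\n")


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=True
    )
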