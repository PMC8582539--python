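"""Per-sample genome-wide aberration burden summaries.

Percent genome altered (PGA) is computed at gene resolution — the fraction of
genes in the included universe carrying a non-neutral thresholded call.  That
is the only resolution available from gene-level calls; no segment lengths
are modeled.  Sex chromosomes are excluded by default, and whole arms (e.g.
the contrasted 3p arm) can be dropped from the universe for stratified
comparisons.
"""

from __future__ import annotations

import pandas as pd

from .model import CnaCallMatrix, build_arm_index


def pga_universe(matrix: CnaCallMatrix, exclude_arms=(),
                 include_sex_chromosomes: bool = False) -> list[str]:
    """Genes contributing to PGA under the given options.

    Requires gene annotations when arms must be excluded or sex chromosomes
    dropped; with no annotations and default options the full gene list is
    used.
    """
    exclude_arms = {tuple(a) for a in exclude_arms}
    if matrix.annotations is None:
        if exclude_arms or include_sex_chromosomes:
            raise ValueError("matrix has no gene annotations; cannot filter")
        return matrix.genes
    index = build_arm_index(matrix.annotations)
    universe = []
    for (chrom, arm), genes in index.items():
        if (chrom, arm) in exclude_arms:
            continue
        if not include_sex_chromosomes and chrom in ("X", "Y"):
            continue
        universe.extend(genes)
    return [g for g in matrix.genes if g in set(universe)]


def percent_genome_altered(matrix: CnaCallMatrix, sample: str,
                           exclude_arms=(), include_sex_chromosomes: bool = False
                           ) -> float:
    universe = pga_universe(matrix, exclude_arms, include_sex_chromosomes)
    if not universe:
        raise ValueError("empty PGA gene universe")
    calls = matrix.sample_calls(sample, universe)
    return float((calls != 0).mean())


def mutation_load(snvs: pd.DataFrame, sample: str,
                  nonsynonymous_only: bool = True) -> int:
    """Count of mutation records for one sample, optionally restricted to
    non-synonymous variants.  A sample absent from the table has load 0."""
    rows = snvs[snvs["sample"] == sample]
    if nonsynonymous_only:
        rows = rows[~rows["synonymous"]]
    return int(len(rows))


def burden_table(matrix: CnaCallMatrix, snvs: pd.DataFrame | None = None,
                 exclude_arms=(), include_sex_chromosomes: bool = False
                 ) -> pd.DataFrame:
    universe = pga_universe(matrix, exclude_arms, include_sex_chromosomes)
    if not universe:
        raise ValueError("empty PGA gene universe")
    sub = matrix.calls.loc[universe]
    pga = (sub != 0).mean(axis=0)
    out = pd.DataFrame({"sample": matrix.samples,
                        "pga": [float(pga[s]) for s in matrix.samples]})
    if snvs is not None:
        loads = snvs[~snvs["synonymous"]].groupby("sample").size()
        out["mutation_load"] = [int(loads.get(s, 0)) for s in matrix.samples]
    return out
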