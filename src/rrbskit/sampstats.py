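"""Sample-level methylome comparison.

A site-by-sample level matrix is built over cytosines of one context that
are covered in every sample, then summarised by Pearson correlation and by
PCA on mean-centred sites; context-by-feature summaries report pooled
methylation per sequence context within annotation classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bscore import MethylomeTable
from .synthio import ReferenceGenome


@dataclass
class SiteMatrix:
    """Rows = cytosine sites, columns = samples, entries = levels."""

    levels: pd.DataFrame  # MultiIndex (chrom, pos, strand) x sample columns

    @property
    def samples(self) -> List[str]:
        return list(self.levels.columns)

    def to_tsv(self, path) -> None:
        self.levels.reset_index().to_csv(path, sep="\t", index=False)


def build_matrix(
    tables: Sequence[MethylomeTable], context: str = "CpG", min_cov: int = 5
) -> SiteMatrix:
    """Intersect qualifying sites across all samples into a level matrix."""
    if len(tables) < 2:
        raise ValueError("need at least two samples")
    cols = {}
    keysets = {}
    for t in tables:
        df = t.sites
        df = df[(df["context"] == context) & (df["mc"] + df["uc"] >= min_cov)]
        s = df.set_index(["chrom", "pos", "strand"])["level"]
        cols[t.sample] = s
        keysets[t.sample] = set(s.index)
    common = set.intersection(*keysets.values())
    if not common:
        limiting = min(keysets, key=lambda k: len(keysets[k]))
        raise ValueError(
            f"no {context} site is covered >= {min_cov}x in every sample "
            f"(fewest qualifying sites: {limiting!r})"
        )
    idx = pd.MultiIndex.from_tuples(sorted(common), names=["chrom", "pos", "strand"])
    mat = pd.DataFrame({name: s.reindex(idx) for name, s in cols.items()})
    return SiteMatrix(mat)


def pearson_matrix(m: SiteMatrix) -> pd.DataFrame:
    """Sample-by-sample Pearson correlation; zero-variance columns give NaN."""
    X = m.levels.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two sites")
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))
    k = X.shape[1]
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            if norms[i] > 0 and norms[j] > 0:
                out[i, j] = float((Xc[:, i] * Xc[:, j]).sum() / (norms[i] * norms[j]))
            elif i == j and norms[i] == 0:
                out[i, j] = np.nan
    return pd.DataFrame(out, index=m.samples, columns=m.samples)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components
    variance_explained: np.ndarray  # fractions over all components
    loadings: np.ndarray  # components x sites

    def to_csv(self, path) -> None:
        df = self.coordinates.copy()
        df.loc["variance_explained"] = np.concatenate(
            [self.variance_explained, np.zeros(df.shape[1] - len(self.variance_explained))]
        )[: df.shape[1]]
        df.to_csv(path)


def pca_samples(m: SiteMatrix, n_components: Optional[int] = None) -> PCAResult:
    """PCA of samples over site-wise mean-centred levels (no scaling).

    Variance-explained fractions sum to 1 over all components; each
    component's sign is fixed so that its first nonzero site loading is
    positive.
    """
    X = m.levels.to_numpy(float).T  # samples x sites
    n_samp = X.shape[0]
    if n_samp < 2:
        raise ValueError("need at least two samples")
    Xc = X - X.mean(axis=0)  # centre each site
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    max_comp = n_samp - 1
    if n_components is None:
        n_components = max_comp
    elif n_components > max_comp:
        import warnings

        warnings.warn(
            f"only {max_comp} components available for {n_samp} samples; truncating"
        )
        n_components = max_comp
    ev = S**2
    frac = ev / ev.sum() if ev.sum() > 0 else np.zeros_like(ev)
    coords = U * S
    # sign convention: first nonzero loading positive
    for c in range(len(S)):
        nz = np.nonzero(np.abs(Vt[c]) > 1e-12)[0]
        if len(nz) and Vt[c, nz[0]] < 0:
            Vt[c] *= -1
            coords[:, c] *= -1
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        pd.DataFrame(coords[:, :n_components], index=m.samples, columns=cols),
        frac[:max_comp],
        Vt[:n_components],
    )


FEATURE_CLASSES = ("promoter", "CGI", "gene_body", "genome_wide")


def context_feature_summary(
    table: MethylomeTable, genome: ReferenceGenome
) -> pd.DataFrame:
    """Coverage-pooled mean level per (context x feature class).

    Feature classes: promoter, CGI, gene body and genome-wide.  A class
    with no qualifying site of a context is reported as NaN (undefined),
    never 0.
    """
    df = table.sites
    kind_map = {"promoter": "promoter", "CGI": "CGI", "gene_body": "gene"}
    rows = []
    for context in ("CpG", "CHG", "CHH"):
        sub = df[df["context"] == context]
        for fclass in FEATURE_CLASSES:
            if fclass == "genome_wide":
                sel = sub
            else:
                mask = np.zeros(len(sub), bool)
                pos = sub["pos"].to_numpy()
                chroms = sub["chrom"].to_numpy()
                for f in genome.features_of(kind_map[fclass]):
                    mask |= (chroms == f.chrom) & (pos >= f.start) & (pos < f.end)
                sel = sub[mask]
            tot = (sel["mc"] + sel["uc"]).sum()
            level = float(sel["mc"].sum() / tot) if tot > 0 else np.nan
            rows.append((context, fclass, len(sel), level))
    return pd.DataFrame(rows, columns=["context", "feature_class", "n_sites", "mean_level"])
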