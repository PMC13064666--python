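"""Non-focal community analytics.

Focal-read fractions, Shannon alpha diversity (natural log), Bray-Curtis
dissimilarity, principal-coordinates ordination, and source attribution of
non-focal taxa against the pre-deployment carrier soil. Diversity and
ordination exclude the focal species by default, since the questions they
answer concern the contaminant community around it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio.diversity.alpha import shannon as _skbio_shannon
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa


@dataclass
class CommunityTable:
    """Taxon x sample read counts with sample metadata and a focal taxon."""

    counts: pd.DataFrame     # index taxa, columns sample ids
    meta: pd.DataFrame       # index sample_id; site, timepoint, ...
    focal_taxon: str

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.focal_taxon not in self.counts.index:
            raise ValueError(f"focal taxon {self.focal_taxon!r} not in table")

    @property
    def taxa(self) -> list:
        return self.counts.index.tolist()

    @property
    def sample_ids(self) -> list:
        return self.counts.columns.tolist()

    def nonfocal_counts(self) -> pd.DataFrame:
        return self.counts.drop(index=self.focal_taxon)


def focal_fraction(table: CommunityTable) -> pd.Series:
    """Percentage of each sample's reads classified as the focal taxon.

    Zero-total samples yield NaN with a warning rather than an error.
    """
    totals = table.counts.sum(axis=0)
    if (totals == 0).any():
        warnings.warn("zero-total sample(s) in focal_fraction; reported NaN")
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = 100.0 * table.counts.loc[table.focal_taxon] / totals
    return frac.rename("focal_pct")


def shannon(counts, exclude_focal: bool = True) -> float | pd.Series:
    """Shannon diversity H = -sum p_i ln p_i (natural log).

    Accepts a single count vector, or a :class:`CommunityTable` (per-sample
    Series returned, focal taxon excluded by default). Zero-count taxa
    contribute nothing; an all-zero vector is an error.
    """
    if isinstance(counts, CommunityTable):
        tbl = counts.nonfocal_counts() if exclude_focal else counts.counts
        return pd.Series(
            {sid: shannon(tbl[sid].to_numpy()) for sid in tbl.columns},
            name="shannon")
    vec = np.asarray(counts, dtype=float)
    if vec.sum() <= 0:
        raise ValueError("Shannon diversity of an all-zero vector is undefined")
    return float(_skbio_shannon(vec[vec > 0], base=math.e))


def bray_curtis(table: CommunityTable,
                exclude_focal: bool = True) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity on raw counts:
    BC(a, b) = sum|a_i - b_i| / sum(a_i + b_i).

    A pair of all-zero samples has an undefined distance; it is reported as
    0 with a warning (skbio requires a hollow, finite matrix).
    """
    counts = (table.nonfocal_counts() if exclude_focal else table.counts)
    mat = counts.to_numpy(float).T          # samples x taxa
    ids = counts.columns.tolist()
    if len(ids) < 2:
        raise ValueError("Bray-Curtis needs >= 2 samples")
    if (mat.sum(axis=1) == 0).any():
        warnings.warn("all-zero sample(s): Bray-Curtis undefined for those "
                      "pairs, reported as 0")
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (mat[i] + mat[j]).sum()
            d = float(np.abs(mat[i] - mat[j]).sum() / denom) if denom else 0.0
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=ids)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame        # samples x axes
    proportion_explained: pd.Series  # over positive eigenvalues only
    eigenvalues: pd.Series           # all, including negative ones


def pcoa(distances: DistanceMatrix, n_axes: int = 2) -> PcoaResult:
    """Classical metric scaling of a dissimilarity matrix.

    Double-centers -0.5 * D^2 and eigendecomposes; axes are ranked by
    eigenvalue. Negative eigenvalues (non-Euclidean input) are reported but
    excluded from the variance-explained denominator; requesting more axes
    than there are positive eigenvalues truncates with a warning.
    """
    with warnings.catch_warnings():
        # skbio warns about full-dimension eigh cost and small negative
        # eigenvalues; both are expected and handled here
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(distances, method="eigh")
    eig = res.eigvals
    pos = eig[eig > 1e-12]
    n_pos = len(pos)
    if n_axes > n_pos:
        warnings.warn(f"requested {n_axes} axes but only {n_pos} positive "
                      "eigenvalues; truncating")
        n_axes = n_pos
    axes = [f"PC{i+1}" for i in range(n_axes)]
    coords = res.samples.iloc[:, :n_axes].copy()
    coords.columns = axes
    coords.index = pd.Index(distances.ids, name="sample_id")
    prop = pd.Series((pos[:n_axes] / pos.sum()).to_numpy(), index=axes,
                     name="proportion_explained")
    return PcoaResult(coordinates=coords, proportion_explained=prop,
                      eigenvalues=pd.Series(eig.to_numpy(),
                                            name="eigenvalue"))


CATEGORIES = ("pre_deployment", "other_site", "site_exclusive")


@dataclass
class SourceAttribution:
    """Origin classification of non-focal taxa, per burial site.

    ``taxon_categories``: long DataFrame (site, taxon, category);
    ``percentages``: per-site read percentages over the three exclusive,
    exhaustive categories (rows sum to 100).
    """

    taxon_categories: pd.DataFrame
    percentages: pd.DataFrame

    def __post_init__(self):
        sums = self.percentages.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("category percentages must sum to 100 per site")


def attribute_sources(site_tables: dict, pre_table: pd.DataFrame | pd.Series,
                      focal_taxon: str, min_count: int = 1
                      ) -> SourceAttribution:
    """Classify every non-focal taxon detected in each site's aChips.

    Rule order: detected in the pre-deployment carrier soil ->
    ``pre_deployment``; else detected in >= 1 other site's aChips ->
    ``other_site``; else ``site_exclusive``. ``site_tables`` maps site ->
    taxon x sample count DataFrame (or CommunityTable); detection is
    count >= ``min_count`` in any sample. Percentages are read-weighted over
    each site's aChip set.
    """
    def frame(t):
        return t.counts if isinstance(t, CommunityTable) else pd.DataFrame(t)

    pre = pd.DataFrame(pre_table).sum(axis=1)
    site_frames = {s: frame(t) for s, t in site_tables.items()}
    detected = {s: set(f.index[(f >= min_count).any(axis=1)]) - {focal_taxon}
                for s, f in site_frames.items()}
    pre_detected = set(pre.index[pre >= min_count]) - {focal_taxon}

    rows, pct_rows = [], {}
    for site, f in site_frames.items():
        nonfocal = f.drop(index=focal_taxon, errors="ignore")
        reads = {c: 0.0 for c in CATEGORIES}
        for taxon in sorted(detected[site]):
            if taxon in pre_detected:
                cat = "pre_deployment"
            elif any(taxon in detected[o] for o in detected if o != site):
                cat = "other_site"
            else:
                cat = "site_exclusive"
            rows.append((site, taxon, cat))
            reads[cat] += float(nonfocal.loc[taxon].sum())
        total = sum(reads.values())
        if total == 0:
            pct_rows[site] = {c: (100.0 if c == "pre_deployment" else 0.0)
                              for c in CATEGORIES}
        else:
            pct_rows[site] = {c: 100.0 * v / total for c, v in reads.items()}

    taxon_categories = pd.DataFrame(rows, columns=["site", "taxon", "category"])
    percentages = pd.DataFrame(pct_rows).T[list(CATEGORIES)]
    percentages.index.name = "site"
    return SourceAttribution(taxon_categories=taxon_categories,
                             percentages=percentages)
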