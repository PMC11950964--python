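"""Patristic distances and mean pairwise phylogenetic distance (MPD).

The patristic distance between two tips is the sum of branch lengths on
the unique path connecting them.  Plot-level MPD is the mean patristic
distance over pairs of species co-occurring in the plot (unweighted by
default; an abundance-weighted variant with weights a_j * a_k is
available).  A species-level MPD predictor is lifted from plot values,
by default as the mean plot MPD over the plots where the species occurs,
mirroring how plot-level environments are lifted to species level.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_tree",
    "patristic_distances",
    "mpd_per_site",
    "species_level_mpd",
]

#: tip pruned automatically when present in the tree but not the community
DEFAULT_OUTGROUP = "Amborella trichopoda"


def read_tree(source) -> dendropy.Tree:
    """Read a rooted Newick tree (path, file object, or string)."""
    if isinstance(source, dendropy.Tree):
        return source
    if hasattr(source, "read"):
        data = source.read()
    else:
        text = str(source)
        if text.lstrip().startswith("(") or ";" in text:
            data = text
        else:
            with open(text) as fh:
                data = fh.read()
    try:
        return dendropy.Tree.get(data=data, schema="newick", preserve_underscores=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc}") from exc


def patristic_distances(tree, prune_to=None) -> pd.DataFrame:
    """Tip-to-tip path-length matrix as a labeled symmetric DataFrame.

    Parameters
    ----------
    tree : dendropy.Tree, path, or Newick string
    prune_to : iterable of str, optional
        Community species labels. Extra tips (e.g. an outgroup) are pruned;
        community species missing from the tree are a hard error.
    """
    tree = read_tree(tree)
    tree = tree.clone(depth=1)
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter() if leaf.taxon]
    if len(labels) != len(set(labels)):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate tip labels in tree: {dupes}")
    if prune_to is not None:
        wanted = [str(s) for s in prune_to]
        missing = sorted(set(wanted) - set(labels))
        if missing:
            raise ValueError(
                f"community species missing from the tree: {missing}; "
                "resolve with proxy tips before analysis"
            )
        keep = set(wanted)
        if len(keep) < len(labels):
            tree.retain_taxa_with_labels(list(keep))
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node.taxon.label if edge.head_node.taxon else "<internal>"
            raise ValueError(f"edge above node {head!r} has no branch length")
        if edge.length < 0:
            raise ValueError("negative branch length in tree")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((leaf.taxon for leaf in tree.leaf_node_iter() if leaf.taxon),
                  key=lambda t: t.label)
    tips = [t.label for t in taxa]
    n = len(tips)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=tips, columns=tips)


def mpd_per_site(Y, D: pd.DataFrame, weighted: bool = False) -> pd.Series:
    """Plot-level mean pairwise phylogenetic distance.

    Unweighted (default): mean of patristic distances over unordered pairs
    of species present in the plot.  Weighted: mean with weights a_j * a_k
    over ordered pairs j != k.  Plots with fewer than two species have no
    pairs; their MPD is NaN (flagged, never silently zero).
    """
    df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
    species = [str(c) for c in df.columns]
    missing = sorted(set(species) - set(map(str, D.index)))
    if missing:
        raise ValueError(f"species absent from distance matrix: {missing}")
    Dsub = D.loc[species, species].to_numpy(dtype=float)
    A = df.to_numpy(dtype=float)
    out = np.full(df.shape[0], np.nan)
    for i in range(df.shape[0]):
        pres = A[i] > 0
        k = int(pres.sum())
        if k < 2:
            continue
        sub = Dsub[np.ix_(pres, pres)]
        if weighted:
            w = A[i, pres]
            W = np.outer(w, w)
            np.fill_diagonal(W, 0.0)
            out[i] = float((sub * W).sum() / W.sum())
        else:
            iu = np.triu_indices(k, 1)
            out[i] = float(sub[iu].mean())
    return pd.Series(out, index=df.index, name="mpd")


def species_level_mpd(Y, mpd_sites: pd.Series, method: str = "occupancy-mean",
                      D: pd.DataFrame | None = None) -> pd.Series:
    """Lift plot-level MPD to a per-species predictor.

    ``occupancy-mean`` (default): mean of plot MPD over plots where the
    species occurs, skipping plots whose MPD is undefined.  A species whose
    occupied plots all lack MPD gets NaN (flagged missing).

    ``focal-distance``: mean patristic distance from the focal species to
    the species it co-occurs with, averaged over occupied plots (requires
    ``D``).
    """
    df = Y if isinstance(Y, pd.DataFrame) else pd.DataFrame(np.asarray(Y, float))
    A = df.to_numpy(dtype=float)
    if method == "occupancy-mean":
        m = mpd_sites.reindex(df.index).to_numpy(dtype=float)
        vals = []
        for j in range(df.shape[1]):
            occ = A[:, j] > 0
            mj = m[occ]
            mj = mj[~np.isnan(mj)]
            vals.append(float(mj.mean()) if mj.size else np.nan)
        return pd.Series(vals, index=df.columns, name="species_mpd")
    if method == "focal-distance":
        if D is None:
            raise ValueError("focal-distance lift requires the patristic matrix")
        species = [str(c) for c in df.columns]
        Dsub = D.loc[species, species].to_numpy(dtype=float)
        vals = []
        for j in range(df.shape[1]):
            per_plot = []
            for i in range(df.shape[0]):
                if A[i, j] <= 0:
                    continue
                others = (A[i] > 0) & (np.arange(df.shape[1]) != j)
                if others.any():
                    per_plot.append(float(Dsub[j, others].mean()))
            vals.append(float(np.mean(per_plot)) if per_plot else np.nan)
        return pd.Series(vals, index=df.columns, name="species_mpd")
    raise ValueError(f"unknown species-level MPD lift {method!r}")
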