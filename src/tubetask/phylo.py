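"""Tree handling, Pagel's lambda, and Brownian-motion ancestral states.

Continuous traits evolving on a rooted, time-calibrated tree are modelled as
multivariate normal with covariance ``sigma2 * C``, where ``C[i, j]`` is the
branch length shared between tips i and j (root-to-MRCA path).  Pagel's
lambda scales the off-diagonal entries of C: lambda = 1 recovers Brownian
motion, lambda = 0 erases all phylogenetic covariance.  The ML fit profiles
the mean and rate analytically and optimizes lambda on [0, 1]; the no-signal
null (lambda = 0) is assessed with a likelihood-ratio test against a
chi-square with one degree of freedom (conservative at the lambda = 0
boundary).

Ancestral states under Brownian motion are the joint maximum-likelihood
(equivalently GLS) estimates of the internal node values; the root estimate
coincides with the GLS mean of the tip data.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize, stats

_LAMBDA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)  # multistart brackets for Brent
_LAMBDA_XATOL = 1e-8


class TreeError(ValueError):
    pass


class Phylogeny:
    """Rooted tree with branch lengths, wrapping a dendropy Tree.

    Tips are labelled with species names; internal nodes get stable ids
    ``node0, node1, ...`` in preorder.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_internal()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted parse errors
            raise TreeError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        out = io.StringIO()
        self._tree.write(file=out, schema="newick", suppress_rooting=True,
                         unquoted_underscores=True)
        return out.getvalue().strip()

    def _label_internal(self) -> None:
        i = 0
        for node in self._tree.preorder_node_iter():
            if node.is_internal() and not getattr(node, "label", None):
                node.label = f"node{i}"
            i += 1

    # -- basics ----------------------------------------------------------
    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    def __len__(self) -> int:
        return len(self._tree.leaf_nodes())

    def copy(self) -> "Phylogeny":
        # round-trip through newick: dendropy's shallow clone shares Taxon
        # objects, so in-place relabeling would leak into the source tree
        return Phylogeny.from_newick(self.to_newick())

    def _depths(self) -> dict:
        """Distance from root for every node."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
        return depths

    def height(self) -> float:
        depths = self._depths()
        return max(d for n, d in depths.items() if n.is_leaf())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        depths = self._depths()
        tip_d = [d for n, d in depths.items() if n.is_leaf()]
        h = max(tip_d)
        return h == 0 or (h - min(tip_d)) <= rel_tol * h

    # -- manipulation ----------------------------------------------------
    def substitute_tips(self, mapping: Mapping[str, str]) -> "Phylogeny":
        """Rename tips; topology and branch lengths are untouched."""
        new = self.copy()
        labels = set(new.tips)
        for old in mapping:
            if old not in labels:
                raise TreeError(f"tip {old!r} not in tree")
        for leaf in new._tree.leaf_node_iter():
            if leaf.taxon.label in mapping:
                leaf.taxon.label = mapping[leaf.taxon.label]
        return new

    def graft_tip(self, new_tip: str, sister: str, divergence_time: float) -> "Phylogeny":
        """Attach a new tip as sister to an existing one.

        ``divergence_time`` is measured back from the sister tip (time before
        present on an ultrametric tree); it must not exceed the sister's
        terminal branch length, so the graft preserves ultrametricity.
        """
        new = self.copy()
        target = None
        for leaf in new._tree.leaf_node_iter():
            if leaf.taxon.label == sister:
                target = leaf
                break
        if target is None:
            raise TreeError(f"sister tip {sister!r} not in tree")
        terminal = target.edge.length or 0.0
        if not 0.0 < divergence_time <= terminal:
            raise TreeError(
                f"divergence time {divergence_time} infeasible for terminal "
                f"branch of length {terminal}"
            )
        parent = target.parent_node
        joint = dendropy.Node()
        joint.edge.length = terminal - divergence_time
        parent.remove_child(target)
        parent.add_child(joint)
        target.edge.length = divergence_time
        joint.add_child(target)
        fresh = dendropy.Node()
        fresh.taxon = new._tree.taxon_namespace.new_taxon(label=new_tip)
        fresh.edge.length = divergence_time
        joint.add_child(fresh)
        return Phylogeny(new._tree)

    def mrca(self, tip_labels: Sequence[str]):
        """Most recent common ancestor node label; a single tip is its own MRCA."""
        if not tip_labels:
            raise TreeError("mrca of an empty tip set")
        missing = set(tip_labels) - set(self.tips)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        if len(set(tip_labels)) == 1:
            return tip_labels[0]
        leaf = {n.taxon.label: n for n in self._tree.leaf_node_iter()}
        paths = []
        for lab in set(tip_labels):
            node, path = leaf[lab], []
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths.append(path[::-1])
        k = min(len(p) for p in paths) - 1
        while not all(p[k] is paths[0][k] for p in paths):
            k -= 1
        node = paths[0][k]
        return node.label if node.label else node.taxon.label

    # -- covariance ------------------------------------------------------
    def vcv(self, tips: Sequence[str] | None = None) -> np.ndarray:
        """Phylogenetic variance-covariance matrix C for the given tip order."""
        order = list(tips) if tips is not None else self.tips
        missing = set(order) - set(self.tips)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        depths = self._depths()
        leaf = {n.taxon.label: n for n in self._tree.leaf_node_iter()}
        # ancestor sets via preorder paths
        paths = {}
        for lab in order:
            node, path = leaf[lab], []
            while node is not None:
                path.append(node)
                node = node.parent_node
            paths[lab] = path[::-1]
        n = len(order)
        C = np.empty((n, n))
        for i, a in enumerate(order):
            pa = paths[a]
            for j in range(i, n):
                pb = paths[order[j]]
                k = min(len(pa), len(pb)) - 1
                while pa[k] is not pb[k]:
                    k -= 1
                C[i, j] = C[j, i] = depths[pa[k]]
            C[i, i] = depths[leaf[a]]
        return C

    def edges(self) -> list[tuple[str, str, float]]:
        """(parent_label, child_label, branch_length) for every edge."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            child = node.taxon.label if node.is_leaf() else node.label
            parent = node.parent_node.label
            out.append((parent, child, node.edge.length or 0.0))
        return out

    @property
    def root_label(self) -> str:
        return self._tree.seed_node.label


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply off-diagonal entries of C by lambda, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


@dataclass(frozen=True)
class LambdaFit:
    lambda_hat: float
    sigma2_hat: float
    mu_hat: float
    loglik: float
    loglik_lambda0: float
    flat_surface: bool = False

    @property
    def lrt_stat(self) -> float:
        return max(0.0, 2.0 * (self.loglik - self.loglik_lambda0))

    @property
    def p(self) -> float:
        return float(stats.chi2.sf(self.lrt_stat, df=1))


def _profile_loglik(x: np.ndarray, C: np.ndarray, lam: float):
    """Profile log-likelihood over (mu, sigma2) at fixed lambda."""
    n = x.size
    V = lambda_transform(C, lam)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ones = np.ones(n)
    iV1 = np.linalg.solve(L.T, np.linalg.solve(L, ones))
    iVx = np.linalg.solve(L.T, np.linalg.solve(L, x))
    mu = (ones @ iVx) / (ones @ iV1)
    r = x - mu
    iVr = iVx - mu * iV1
    sigma2 = (r @ iVr) / n  # ML estimate
    if sigma2 <= 0:
        return -np.inf, mu, sigma2
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return float(ll), float(mu), float(sigma2)


def fit_lambda(trait: Mapping[str, float], tree: Phylogeny) -> LambdaFit:
    """ML estimate of Pagel's lambda with a likelihood-ratio test vs 0.

    Uses bounded Brent optimization restarted from a coarse grid; on a
    likelihood surface that is flat in lambda (e.g. a star phylogeny) a
    warning is issued and ``flat_surface`` is set.
    """
    species = sorted(trait)
    x = np.array([trait[s] for s in species], dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 tips to fit lambda, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("trait is constant; lambda is undefined")
    if not tree.is_ultrametric():
        warnings.warn("tree is not ultrametric; lambda fit may be distorted")
    C = tree.vcv(species)

    grid_ll = [_profile_loglik(x, C, lam)[0] for lam in _LAMBDA_GRID]
    flat = (max(grid_ll) - min(grid_ll)) < 1e-8
    if flat:
        warnings.warn("log-likelihood is flat in lambda (star-like tree); "
                      "lambda is unidentifiable")
    best = int(np.argmax(grid_ll))
    lo = _LAMBDA_GRID[max(best - 1, 0)]
    hi = _LAMBDA_GRID[min(best + 1, len(_LAMBDA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(x, C, lam)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _LAMBDA_XATOL},
    )
    candidates = [(grid_ll[best], _LAMBDA_GRID[best]), (-res.fun, float(res.x))]
    ll_hat, lam_hat = max(candidates)
    _, mu_hat, s2_hat = _profile_loglik(x, C, lam_hat)
    ll0 = _profile_loglik(x, C, 0.0)[0]
    return LambdaFit(
        lambda_hat=lam_hat,
        sigma2_hat=s2_hat,
        mu_hat=mu_hat,
        loglik=ll_hat,
        loglik_lambda0=ll0,
        flat_surface=flat,
    )


@dataclass(frozen=True)
class NodeEstimate:
    node_id: str
    estimate: float
    variance: float


def asr_bm(trait: Mapping[str, float], tree: Phylogeny) -> dict[str, NodeEstimate]:
    """Joint-ML ancestral states under Brownian motion (untransformed tree).

    The BM likelihood factorizes over edges into independent Gaussian
    increments, so maximizing over internal states solves a sparse weighted
    Laplacian system with tip values fixed.  Variances come from the inverse
    of the internal-block precision, scaled by the ML rate estimate.
    """
    species = sorted(trait)
    if set(species) != set(tree.tips):
        missing = set(tree.tips) ^ set(species)
        raise ValueError(f"trait/tip mismatch: {sorted(missing)}")
    edges = tree.edges()
    # every parent is internal; tips never appear as parents
    internal = list(dict.fromkeys(p for p, _, _ in edges))
    idx_i = {n: k for k, n in enumerate(internal)}
    n_i = len(internal)

    x_t = np.array([trait[s] for s in species])
    idx_t = {s: k for k, s in enumerate(species)}

    L_ii = np.zeros((n_i, n_i))
    b = np.zeros(n_i)
    for parent, child, length in edges:
        w = 1.0 / max(length, 1e-12)
        p_int = parent in idx_i
        c_int = child in idx_i
        if p_int:
            L_ii[idx_i[parent], idx_i[parent]] += w
        if c_int:
            L_ii[idx_i[child], idx_i[child]] += w
        if p_int and c_int:
            L_ii[idx_i[parent], idx_i[child]] -= w
            L_ii[idx_i[child], idx_i[parent]] -= w
        elif p_int:
            b[idx_i[parent]] += w * x_t[idx_t[child]]
        elif c_int:
            b[idx_i[child]] += w * x_t[idx_t[parent]]
    est = np.linalg.solve(L_ii, b)

    # ML rate under BM with the root free: from the GLS fit on the tips.
    C = tree.vcv(species)
    _, _, sigma2 = _profile_loglik(x_t, C, 1.0)
    cov = sigma2 * np.linalg.inv(L_ii)
    return {
        n: NodeEstimate(n, float(est[k]), float(cov[k, k]))
        for n, k in idx_i.items()
    }


def asr_frame(estimates: Mapping[str, NodeEstimate]):
    import pandas as pd

    rows = sorted(estimates.values(), key=lambda e: e.node_id)
    return pd.DataFrame(
        {
            "node_id": [e.node_id for e in rows],
            "estimate": [e.estimate for e in rows],
            "variance": [e.variance for e in rows],
        }
    )
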