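"""Single-step GBLUP evaluation: mixed-model equations, SNP back-solving,
iterative SNP weighting, and window-variance GWAS summaries.

The central objects follow the Model/Results convention:

* :class:`SingleStepModel` holds the data (phenotypes, pedigree, optional
  genotypes), the evaluation scheme, and the variance components.
* :meth:`SingleStepModel.fit` assembles and solves Henderson's mixed-model
  equations with the pedigree inverse A⁻¹ replaced by the single-step H⁻¹,
  and returns a :class:`SingleStepResults` carrying GEBVs, fixed-effect
  solutions, solver diagnostics and (for weighted schemes) the per-SNP
  weights of every iteration.

The animal effects u (stacked trait-major) have covariance G0 ⊗ H and the
residuals honour per-record trait missingness by inverting the R0 submatrix
of each record's observed-trait pattern.

Nine evaluation schemes are supported: the plain single-trait model
(``ST_ss``), its linearly and nonlinearly SNP-weighted variants after one
or two weighting rounds (``ST_sswl1/2``, ``ST_sswnl1/2``), two-trait models
adding the growth or intake helper (``TT_W450``, ``TT_DMI``), a three-trait
model adding both carcass traits (``TTT_CAR``) and the full multi-trait
model (``MT_ss``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .config import check_spd
from .containers import GenotypeMatrix, PedigreeTable
from .errors import ConfigError, DataError, NumericalError
from .kinship import RelationshipSet, build_relationships, vanraden_lambda
from .prep import cg_labels

# scheme -> (helper traits appended after the target, weight scheme, weighting rounds)
SCHEMES: dict[str, tuple[tuple[str, ...], str, int]] = {
    "ST_ss": ((), "identity", 0),
    "ST_sswl1": ((), "linear", 1),
    "ST_sswl2": ((), "linear", 2),
    "ST_sswnl1": ((), "nonlinear", 1),
    "ST_sswnl2": ((), "nonlinear", 2),
    "TT_W450": (("W450",), "identity", 0),
    "TT_DMI": (("DMI",), "identity", 0),
    "TTT_CAR": (("REA", "RFT"), "identity", 0),
    "MT_ss": (("W450", "DMI", "REA", "RFT"), "identity", 0),
}

NONLINEAR_BASE = 1.125
NONLINEAR_EXP_CAP = 5.0  # cap on |u|/sd before the -2 shift


@dataclass
class EvaluationModel:
    """Trait list, scheme and variance components of one evaluation."""

    traits: tuple
    scheme: str
    G0: np.ndarray
    R0: np.ndarray
    weight_scheme: str = "identity"
    weight_rounds: int = 0

    @classmethod
    def from_scheme(cls, scheme: str, target: str, G0_full: np.ndarray,
                    R0_full: np.ndarray, trait_names) -> "EvaluationModel":
        """Build the model for a named scheme, slicing the full covariance
        matrices down to the scheme's trait set (target trait first)."""
        if scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {scheme!r}; valid: {sorted(SCHEMES)}")
        helpers, wscheme, rounds = SCHEMES[scheme]
        names = list(trait_names)
        if target not in names:
            raise ConfigError(f"target trait {target!r} not among {names}")
        absent = [h for h in helpers if h not in names and h != target]
        if absent:
            if len(absent) == len(helpers):
                raise ConfigError(f"scheme {scheme} needs helper trait(s) {list(helpers)}")
            warnings.warn(f"scheme {scheme}: helper trait(s) {absent} not simulated; "
                          "using the available ones")
        traits = (target,) + tuple(h for h in helpers if h != target and h in names)
        idx = [names.index(t) for t in traits]
        sub = np.ix_(idx, idx)
        return cls(traits=traits, scheme=scheme,
                   G0=np.asarray(G0_full)[sub], R0=np.asarray(R0_full)[sub],
                   weight_scheme=wscheme, weight_rounds=rounds)

    def __post_init__(self):
        self.traits = tuple(self.traits)
        t = len(self.traits)
        self.G0 = check_spd(np.atleast_2d(np.asarray(self.G0, dtype=float)), "G0")
        self.R0 = check_spd(np.atleast_2d(np.asarray(self.R0, dtype=float)), "R0")
        if self.G0.shape != (t, t) or self.R0.shape != (t, t):
            raise ConfigError("G0/R0 dimensions must match the trait list")
        if self.weight_scheme not in ("identity", "linear", "nonlinear"):
            raise ConfigError(f"unknown weight scheme {self.weight_scheme!r}")
        if self.weight_scheme != "identity" and len(self.traits) != 1:
            raise ConfigError("SNP weighting applies to single-trait schemes only")


@dataclass
class MMESystem:
    """Assembled mixed-model equations (sparse, symmetric)."""

    lhs: sp.csr_matrix
    rhs: np.ndarray
    traits: tuple
    animal_ids: np.ndarray  # pedigree order; u columns follow this order per trait
    beta_index: list  # (trait, cg_label) per fixed-effect equation
    n_beta: int


def assemble_mme(phen: pd.DataFrame, model: EvaluationModel,
                 ped: PedigreeTable, K_inv: sp.spmatrix) -> MMESystem:
    """Henderson's MME with contemporary-group fixed effects per trait and
    additive animal effects with covariance G0 ⊗ K (K = H or A).

    ``K_inv`` is the (sparse) inverse relationship matrix over the full
    pedigree. One phenotype row per animal; a missing trait value simply
    contributes no record for that trait, and the residual covariance of
    each record is the R0 submatrix of its observed-trait pattern.
    """
    traits = list(model.traits)
    t = len(traits)
    n = len(ped)
    if K_inv.shape != (n, n):
        raise ConfigError("relationship inverse does not match pedigree size")
    for tr in traits:
        if tr not in phen.columns:
            raise DataError(f"phenotype table has no column {tr!r}")
    if phen["animal"].duplicated().any():
        raise DataError("one phenotype row per animal expected")

    prow = ped.index_of(phen["animal"].to_numpy())  # pedigree row per record
    y = phen[traits].to_numpy(dtype=float)

    # fixed-effect (CG) columns per trait, from observed records only
    beta_index: list[tuple[str, str]] = []
    beta_col = np.full((len(phen), t), -1, dtype=int)
    for j, tr in enumerate(traits):
        lab = cg_labels(phen, tr)
        obs = lab.notna().to_numpy()
        if not obs.any():
            continue
        codes, levels = pd.factorize(lab[obs], sort=True)
        start = len(beta_index)
        beta_index.extend((tr, lv) for lv in levels)
        beta_col[obs, j] = start + codes
    n_beta = len(beta_index)
    missing_cg = (~np.isnan(y)) & (beta_col < 0)
    if missing_cg.any():
        i, j = np.argwhere(missing_cg)[0]
        raise DataError(
            f"record for animal {phen['animal'].iloc[i]} trait {traits[j]} has no CG"
        )

    neq = n_beta + t * n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    rhs = np.zeros(neq)

    def ucol(j, rows_):  # global u-equation index, trait-major
        return n_beta + j * n + prow[rows_]

    patt = ~np.isnan(y)
    for pattern in np.unique(patt, axis=0):
        if not pattern.any():
            continue
        g = np.flatnonzero((patt == pattern).all(axis=1))
        S = np.flatnonzero(pattern)
        r_inv = np.linalg.inv(model.R0[np.ix_(S, S)])
        for a, t1 in enumerate(S):
            for b, t2 in enumerate(S):
                w = r_inv[a, b]
                bc1, bc2 = beta_col[g, t1], beta_col[g, t2]
                u1, u2 = ucol(t1, g), ucol(t2, g)
                wv = np.full(len(g), w)
                rows += [bc1, bc1, u1, u1]
                cols += [bc2, u2, bc2, u2]
                vals += [wv, wv, wv, wv]
                np.add.at(rhs, bc1, w * y[g, t2])
                np.add.at(rhs, u1, w * y[g, t2])

    C = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(neq, neq),
    ).tocsr()
    G0_inv = np.linalg.inv(model.G0)
    penalty = sp.kron(sp.csr_matrix(G0_inv), sp.csr_matrix(K_inv), format="csr")
    pad = sp.block_diag(
        [sp.csr_matrix((n_beta, n_beta)), penalty], format="csr"
    )
    return MMESystem(lhs=C + pad, rhs=rhs, traits=tuple(traits),
                     animal_ids=ped.ids, beta_index=beta_index, n_beta=n_beta)


@dataclass
class GEBVSet:
    """Estimated breeding values per animal per trait, plus solver state."""

    gebv: pd.DataFrame  # index = animal id, one column per trait
    fixed_effects: pd.DataFrame  # trait, cg, estimate
    dataset_tag: str = "whole"
    diagnostics: dict = field(default_factory=dict)

    def for_animals(self, ids, trait: str | None = None):
        col = trait or self.gebv.columns[0]
        return self.gebv.loc[np.asarray(ids), col].to_numpy()


def solve_mme(system: MMESystem, method: str = "pcg", rtol: float = 1e-12,
              maxiter: int | None = None, dataset_tag: str = "whole") -> GEBVSet:
    """Solve the MME; Jacobi-preconditioned conjugate gradients by default.

    Deterministic given inputs (fixed equation ordering, no stochastic
    preconditioning). Falls back with a warning if CG hits the iteration
    cap without reaching the requested relative residual.
    """
    A, b = system.lhs, system.rhs
    neq = A.shape[0]
    info = 0
    iters = [0]
    if method == "direct":
        sol = spla.spsolve(A.tocsc(), b)
    elif method == "pcg":
        d = A.diagonal()
        if np.any(d <= 0):
            raise NumericalError("non-positive diagonal in MME; system is singular")
        M = spla.LinearOperator((neq, neq), matvec=lambda x: x / d)

        def cb(_):
            iters[0] += 1

        sol, info = spla.cg(A, b, rtol=rtol, atol=0.0,
                            maxiter=maxiter or max(20 * neq, 1000), M=M, callback=cb)
        if info > 0:
            warnings.warn(f"PCG stopped at {info} iterations above tolerance")
        elif info < 0:
            raise NumericalError("PCG failed (illegal input or breakdown)")
    else:
        raise ConfigError(f"unknown solver method {method!r}")

    res = float(np.linalg.norm(A @ sol - b) / max(np.linalg.norm(b), 1e-300))
    n = len(system.animal_ids)
    u = sol[system.n_beta:].reshape(len(system.traits), n).T
    gebv = pd.DataFrame(u, index=pd.Index(system.animal_ids, name="animal"),
                        columns=list(system.traits))
    fx = pd.DataFrame(
        [(tr, cg, est) for (tr, cg), est in zip(system.beta_index, sol[:system.n_beta])],
        columns=["trait", "cg", "estimate"],
    )
    return GEBVSet(gebv=gebv, fixed_effects=fx, dataset_tag=dataset_tag,
                   diagnostics={"method": method, "iterations": iters[0],
                                "relative_residual": res, "n_equations": neq})


# ---------------------------------------------------------------------------
# SNP effects, weights, windows
# ---------------------------------------------------------------------------

def backsolve_snp_effects(a_g: np.ndarray, geno: GenotypeMatrix,
                          weights: np.ndarray | None = None,
                          lam: float | None = None,
                          ridge: float = 0.0) -> np.ndarray:
    """SNP effects from genotyped-animal GEBVs: û = λ D Z′ (Z D Z′ λ)⁻¹ â_g.

    Z is the 2p-centred genotype matrix of the genotyped animals and D the
    diagonal SNP-weight matrix (identity when ``weights`` is None).
    """
    a_g = np.asarray(a_g, dtype=float)
    if a_g.shape != (geno.n_animals,):
        raise DataError("GEBV vector must cover exactly the genotyped animals")
    m = geno.n_snps
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ConfigError("SNP weights must be non-negative")
    p = geno.allele_freqs()
    Z = geno.imputed() - 2.0 * p
    if lam is None:
        poly = (p > 0) & (p < 1)
        lam = vanraden_lambda(p[poly])
    Gs = (Z * w) @ Z.T * lam
    if ridge > 0:
        Gs = Gs + ridge * np.eye(Gs.shape[0])
    try:
        t = np.linalg.solve(Gs, a_g)
    except np.linalg.LinAlgError:
        raise NumericalError("weighted G* is singular; cannot back-solve SNP effects") from None
    return lam * w * (Z.T @ t)


def snp_variance(effects: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Per-SNP additive variance σ²_{u,i} = û_i² · 2 p_i (1 − p_i)."""
    u = np.asarray(effects, dtype=float)
    p = np.asarray(freqs, dtype=float)
    return u**2 * 2.0 * p * (1.0 - p)


def update_weights_linear(effects: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Linear weights d_i = û_i² · 2 p_i (1 − p_i) (normalise afterwards)."""
    return snp_variance(effects, freqs)


def update_weights_nonlinear(effects: np.ndarray) -> np.ndarray:
    """Nonlinear weights d_i = 1.125^(|û_i|/sd(û) − 2), exponent capped.

    The departure |û|/sd is capped at 5 so a single extreme SNP cannot
    dominate the weighted matrix. With sd(û) = 0 all weights are 1 (warned).
    """
    u = np.abs(np.asarray(effects, dtype=float))
    sd = float(np.std(np.asarray(effects, dtype=float), ddof=0))
    if sd == 0:
        warnings.warn("sd of SNP effects is zero; nonlinear weights set to 1")
        return np.ones_like(u)
    dep = np.minimum(u / sd, NONLINEAR_EXP_CAP)
    return NONLINEAR_BASE ** (dep - 2.0)


def normalize_weights(d: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Rescale weights so Σ d_i · 2p_i(1−p_i) keeps its D = I value,
    preserving the total genetic variance across iterations."""
    d = np.asarray(d, dtype=float)
    p = np.asarray(freqs, dtype=float)
    het = 2.0 * p * (1.0 - p)
    s = float(np.sum(d * het))
    if s <= 0:
        raise NumericalError("all SNP weights are zero; cannot normalise")
    return d * (float(np.sum(het)) / s)


def window_variance(effects: np.ndarray, geno: GenotypeMatrix,
                    window: int = 10, sigma2_a: float | None = None) -> pd.DataFrame:
    """Percent additive variance per window of adjacent SNPs.

    For each non-overlapping window of ``window`` adjacent SNPs (never
    spanning chromosomes; a short chromosome tail forms a truncated window,
    flagged), the variance over genotyped animals of the window's summed
    genotype-weighted effects is divided by σ²_a and scaled to percent.
    σ²_a defaults to the variance of the total genomic value, so shares sum
    to ≈ 100%.
    """
    u = np.asarray(effects, dtype=float)
    if u.shape != (geno.n_snps,):
        raise DataError("one effect per SNP required")
    order = np.lexsort((geno.snp_map["pos"].to_numpy(),
                        geno.snp_map["chrom"].to_numpy()))
    p = geno.allele_freqs()
    Z = geno.imputed() - 2.0 * p
    if sigma2_a is None:
        total = Z @ u
        sigma2_a = float(np.var(total))
    if sigma2_a <= 0:
        sigma2_a = np.inf  # all-zero effects -> all windows 0%
    out = []
    chroms = geno.snp_map["chrom"].to_numpy()[order]
    wid = 0
    for c in pd.unique(chroms):
        snps_c = order[chroms == c]
        for start in range(0, len(snps_c), window):
            idx = snps_c[start:start + window]
            a_w = Z[:, idx] @ u[idx]
            out.append({
                "window": wid, "chrom": c,
                "start_pos": int(geno.snp_map["pos"].iloc[idx[0]]),
                "end_pos": int(geno.snp_map["pos"].iloc[idx[-1]]),
                "n_snps": len(idx),
                "truncated": len(idx) < window,
                "pct_variance": 100.0 * float(np.var(a_w)) / sigma2_a,
            })
            wid += 1
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SingleStepModel:
    """Single-step genomic evaluation model.

    Parameters
    ----------
    phenotypes : DataFrame
        One row per animal: ``animal``, CG factor columns and trait columns.
    pedigree : PedigreeTable
    genotypes : GenotypeMatrix or None
        None reduces every scheme to pedigree BLUP.
    model : EvaluationModel
        Trait set, scheme and variance components (see
        :meth:`EvaluationModel.from_scheme`).
    alpha, tune
        G blending/tuning toward A22 (single-step compatibility).
    relationships : RelationshipSet, optional
        Precomputed A/A⁻¹/F to reuse across schemes; G/H⁻¹ are always
        (re)built for the model's weighting.
    """

    def __init__(self, phenotypes: pd.DataFrame, pedigree: PedigreeTable,
                 genotypes: GenotypeMatrix | None, model: EvaluationModel,
                 alpha: float = 0.05, tune: bool = True,
                 relationships: RelationshipSet | None = None):
        self.phenotypes = phenotypes
        self.pedigree = pedigree
        self.genotypes = genotypes
        self.model = model
        self.alpha = alpha
        self.tune = tune
        self._rel = relationships

    @classmethod
    def from_scheme(cls, scheme: str, target: str, phenotypes, pedigree,
                    genotypes, G0_full, R0_full, trait_names, **kw):
        em = EvaluationModel.from_scheme(scheme, target, G0_full, R0_full, trait_names)
        return cls(phenotypes, pedigree, genotypes, em, **kw)

    def _relationships(self, weights: np.ndarray | None) -> RelationshipSet:
        if weights is None and self._rel is not None and self._rel.H_inv is not None:
            return self._rel
        rel = build_relationships(self.pedigree, self.genotypes, weights=weights,
                                  alpha=self.alpha, tune=self.tune)
        if weights is None:
            self._rel = rel
        return rel

    def fit(self, method: str = "pcg", dataset_tag: str = "whole",
            rtol: float = 1e-12) -> "SingleStepResults":
        """Assemble and solve; weighted schemes run the iterative loop:

        round 0 solves with D = I (the plain ssGBLUP), each further round
        back-solves SNP effects, updates and normalises the weights
        (linear or nonlinear), rebuilds G*/H⁻¹ and re-solves.
        """
        em = self.model
        history: list[dict] = []
        weights = None
        rounds = em.weight_rounds if em.weight_scheme != "identity" else 0
        geno = self.genotypes

        rel = self._relationships(None)
        system = assemble_mme(self.phenotypes, em, self.pedigree, rel.H_inv)
        sol = solve_mme(system, method=method, rtol=rtol, dataset_tag=dataset_tag)

        if rounds and (geno is None or geno.n_animals == 0):
            warnings.warn("no genotypes: weighted scheme reduces to pedigree BLUP")
            rounds = 0
        p = geno.allele_freqs() if geno is not None and geno.n_animals else None

        for it in range(1, rounds + 1):
            a_g = sol.for_animals(geno.ids, em.traits[0])
            u_hat = backsolve_snp_effects(a_g, geno, weights=weights)
            if em.weight_scheme == "linear":
                d = update_weights_linear(u_hat, p)
            else:
                d = update_weights_nonlinear(u_hat)
            weights = normalize_weights(d, p)
            history.append({"iteration": it, "weights": weights, "snp_effects": u_hat})
            rel = self._relationships(weights)
            system = assemble_mme(self.phenotypes, em, self.pedigree, rel.H_inv)
            sol = solve_mme(system, method=method, rtol=rtol, dataset_tag=dataset_tag)

        return SingleStepResults(model=self, evaluation=em, gebv_set=sol,
                                 relationships=rel, weights=weights,
                                 weight_history=history)


class SingleStepResults:
    """Fitted single-step evaluation.

    Attributes
    ----------
    gebv : DataFrame — GEBV per animal (index) per trait (columns).
    fixed_effects : DataFrame — CG solutions per trait.
    weights : ndarray or None — final SNP weights (weighted schemes).
    weight_history : list of per-iteration {iteration, weights, snp_effects}.
    """

    def __init__(self, model: SingleStepModel, evaluation: EvaluationModel,
                 gebv_set: GEBVSet, relationships: RelationshipSet,
                 weights, weight_history):
        self.model = model
        self.evaluation = evaluation
        self.gebv_set = gebv_set
        self.relationships = relationships
        self.weights = weights
        self.weight_history = weight_history

    @property
    def gebv(self) -> pd.DataFrame:
        return self.gebv_set.gebv

    @property
    def fixed_effects(self) -> pd.DataFrame:
        return self.gebv_set.fixed_effects

    @property
    def diagnostics(self) -> dict:
        return self.gebv_set.diagnostics

    def snp_effects(self, trait: str | None = None) -> np.ndarray:
        """Back-solved SNP effects for the (target) trait under the final
        weights."""
        geno = self.model.genotypes
        if geno is None or geno.n_animals == 0:
            raise DataError("no genotypes in the model")
        a_g = self.gebv_set.for_animals(geno.ids, trait or self.evaluation.traits[0])
        return backsolve_snp_effects(a_g, geno, weights=self.weights)

    def window_table(self, window: int = 10, trait: str | None = None) -> pd.DataFrame:
        """Manhattan-ready per-window percent-variance table."""
        return window_variance(self.snp_effects(trait), self.model.genotypes,
                               window=window)

    def summary(self) -> str:
        em = self.evaluation
        g = self.gebv
        d = self.diagnostics
        lines = [
            "Single-step GBLUP results",
            "=" * 54,
            f"scheme:          {em.scheme}",
            f"traits:          {', '.join(em.traits)}",
            f"animals:         {len(g)}",
            f"genotyped:       {0 if self.model.genotypes is None else self.model.genotypes.n_animals}",
            f"equations:       {d.get('n_equations')}",
            f"solver:          {d.get('method')} ({d.get('iterations')} iterations, "
            f"rel. residual {d.get('relative_residual'):.2e})",
            f"dataset:         {self.gebv_set.dataset_tag}",
            "",
            "GEBV summary (per trait):",
        ]
        for tr in em.traits:
            v = g[tr]
            lines.append(f"  {tr:>6}: mean {v.mean():+.4f}  sd {v.std():.4f}  "
                         f"min {v.min():+.4f}  max {v.max():+.4f}")
        if self.weights is not None:
            w = self.weights
            lines += ["", f"SNP weights ({em.weight_scheme}, {len(self.weight_history)} "
                          f"round(s)): mean {w.mean():.4f}  max {w.max():.4f}"]
        return "\n".join(lines)


def run_weighted_iterations(phenotypes, pedigree, genotypes, model: EvaluationModel,
                            n_iter: int, scheme: str = "linear",
                            alpha: float = 0.05, tune: bool = True,
                            method: str = "pcg"):
    """Functional wrapper over the weighting loop.

    Returns the list of per-iteration solutions: iteration 1 solves with
    D = I (identical to ``ST_ss``); iteration t ≥ 2 solves with the
    normalised weights derived from iteration t−1's SNP effects. Each entry
    is ``{"iteration", "gebv_set", "weights"}`` (weights used in that solve).
    """
    if n_iter < 1:
        raise ConfigError("n_iter must be >= 1")
    em = EvaluationModel(traits=model.traits, scheme=model.scheme,
                         G0=model.G0, R0=model.R0,
                         weight_scheme=scheme, weight_rounds=0)
    out = []
    weights = None
    p = genotypes.allele_freqs() if genotypes is not None else None
    for it in range(1, n_iter + 1):
        rel = build_relationships(pedigree, genotypes, weights=weights,
                                  alpha=alpha, tune=tune)
        system = assemble_mme(phenotypes, em, pedigree, rel.H_inv)
        sol = solve_mme(system, method=method)
        out.append({"iteration": it, "gebv_set": sol,
                    "weights": np.ones(genotypes.n_snps) if weights is None and genotypes is not None else weights})
        if it == n_iter or genotypes is None:
            break
        a_g = sol.for_animals(genotypes.ids, em.traits[0])
        u_hat = backsolve_snp_effects(a_g, genotypes, weights=weights)
        d = update_weights_linear(u_hat, p) if scheme == "linear" \
            else update_weights_nonlinear(u_hat)
        weights = normalize_weights(d, p)
    return out
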