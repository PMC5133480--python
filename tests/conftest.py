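import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def kendall_tau_quadrature_oracle():
    """Integral-definition Kendall's tau, tau = 4 * E[C(U,V)] - 1 = 1 - 4*Int Cu*Cv.

    Evaluated by tensor Gauss-Legendre quadrature with the partial
    derivatives of the CDF taken numerically, so the oracle depends on the
    copula only through bb1_cdf and is independent of both the closed-form
    tau and the analytic conditional CDF.
    """
    from copulaqtl import bb1_cdf

    nodes, weights = np.polynomial.legendre.leggauss(120)
    x = 0.5 * (nodes + 1.0)
    w = 0.5 * weights
    U, V = np.meshgrid(x, x)
    W = np.outer(w, w)
    h = 1e-6

    def oracle(params):
        cu = (bb1_cdf(np.clip(U + h, 0, 1), V, params)
              - bb1_cdf(np.clip(U - h, 0, 1), V, params)) / (2 * h)
        cv = (bb1_cdf(U, np.clip(V + h, 0, 1), params)
              - bb1_cdf(U, np.clip(V - h, 0, 1), params)) / (2 * h)
        return 1.0 - 4.0 * float(np.sum(W * cu * cv))

    return oracle


@pytest.fixture(scope="session")
def scan_fixture_paths(tmp_path_factory):
    """Small synthetic study on disk (VCF + TSVs) shared across tests."""
    from copulaqtl import simulate_scan_fixture

    out = tmp_path_factory.mktemp("study")
    return simulate_scan_fixture(str(out), n_genes=6, variants_per_gene=15,
                                 n=81, tau=0.2, seed=20250901)


@pytest.fixture(scope="session")
def adjusted_scan_study(scan_fixture_paths):
    """The fixture study loaded, adjusted and assembled into StudyData."""
    from copulaqtl import StudyData, load_gene_annotations, load_genotype_dosages
    from copulaqtl.phenotypes import adjust_study, load_expression, load_phenotypes

    pheno = load_phenotypes(scan_fixture_paths["phenotypes"])
    expr = load_expression(scan_fixture_paths["expression"])
    adj = adjust_study(pheno, expr)
    variants = load_genotype_dosages(scan_fixture_paths["vcf"], adj.sample_ids)
    genes = load_gene_annotations(scan_fixture_paths["genes"])
    return StudyData(sample_ids=adj.sample_ids, variants=variants, genes=genes,
                     sbp_adj=adj.sbp_adj, ge_adj=adj.ge_adj)


def tobit_testdata(n, treated_fraction, seed, beta=(120.0, 0.5, -3.0, 2.0),
                   sigma=15.0):
    """Censored-regression test generator with retained truth."""
    rng = np.random.default_rng(seed)
    X = np.column_stack([
        np.ones(n),
        rng.uniform(30, 70, n),
        rng.integers(0, 2, n).astype(float),
        (rng.random(n) < 0.25).astype(float),
    ])
    true = X @ np.asarray(beta) + rng.normal(0.0, sigma, n)
    treated = (rng.random(n) < treated_fraction).astype(int)
    obs = true.copy()
    idx = treated == 1
    obs[idx] -= rng.gamma(2.0, 5.0, int(idx.sum()))
    return X, obs, treated, true
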