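"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written as plainly as possible — explicit loops, the
textbook formulas — and never calls into the package's own computational
paths, so agreement between the two is a real cross-check.
"""

import itertools

import numpy as np


def fisher_auc_bruteforce(Xa_train, Xb_train, Xa_test, Xb_test, shrinkage=0.0):
    """AUC of the Fisher discriminant, computed with loops from first principles.

    Pooled covariance (biased, divisor n) of class-demeaned training data,
    shrunk toward (trace/C)*I by a fixed intensity; weight vector is the
    inverse covariance times the class-mean difference (class b positive);
    AUC by exhaustive pair counting with half credit for ties.
    """
    Xa, Xb = np.asarray(Xa_train, float), np.asarray(Xb_train, float)
    C = Xa.shape[1]
    mu_a, mu_b = Xa.mean(axis=0), Xb.mean(axis=0)
    n = len(Xa) + len(Xb)
    S = np.zeros((C, C))
    for x in Xa:
        d = x - mu_a
        S += np.outer(d, d)
    for x in Xb:
        d = x - mu_b
        S += np.outer(d, d)
    S /= n
    S = (1 - shrinkage) * S + shrinkage * (np.trace(S) / C) * np.eye(C)
    w = np.linalg.pinv(S) @ (mu_b - mu_a)
    scores_a = [float(x @ w) for x in np.asarray(Xa_test, float)]
    scores_b = [float(x @ w) for x in np.asarray(Xb_test, float)]
    wins = 0.0
    for sb in scores_b:
        for sa in scores_a:
            if sb > sa:
                wins += 1.0
            elif sb == sa:
                wins += 0.5
    return wins / (len(scores_a) * len(scores_b))


def ledoit_wolf_intensity(Xa_train, Xb_train):
    """Analytic shrinkage intensity, computed with loops from the LW formula."""
    Xa = np.asarray(Xa_train, float) - np.mean(Xa_train, axis=0)
    Xb = np.asarray(Xb_train, float) - np.mean(Xb_train, axis=0)
    X = np.vstack([Xa, Xb])
    n, C = X.shape
    S = sum(np.outer(x, x) for x in X) / n
    mu = np.trace(S) / C
    d2 = np.sum((S - mu * np.eye(C)) ** 2)
    b2 = sum(np.sum((np.outer(x, x) - S) ** 2) for x in X) / n**2
    b2 = min(b2, d2)
    return b2 / d2 if d2 > 0 else 1.0


def partial_spearman_residualization(a, b, control):
    """Partial Spearman by rank -> OLS residualization -> Pearson on residuals."""
    from scipy.stats import rankdata

    ra, rb, rc = rankdata(a), rankdata(b), rankdata(control)

    def residualize(y, x):
        X = np.column_stack([np.ones_like(x), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    ea, eb = residualize(ra, rc), residualize(rb, rc)
    return float(np.corrcoef(ea, eb)[0, 1])


def sign_flip_exact_p(values, alternative="greater"):
    """Exhaustive sign-flip permutation p for the mean of small samples."""
    values = np.asarray(values, float)
    obs = values.mean()
    eps = 1e-9 * max(1.0, abs(obs))  # count float-identical stats as ties
    count, total = 0, 0
    for signs in itertools.product((1.0, -1.0), repeat=values.size):
        stat = float(np.dot(signs, values)) / values.size
        total += 1
        if alternative == "greater" and stat >= obs - eps:
            count += 1
        elif alternative == "less" and stat <= obs + eps:
            count += 1
        elif alternative == "two_sided" and abs(stat) >= abs(obs) - eps:
            count += 1
    return count / total


def pca2_closed_form(x, y):
    """First-PC scores and %variance for two standardized variables.

    For a 2x2 correlation matrix [[1, r], [1, r]] the top eigenvalue is
    1 + |r| and the component is (1, sign(r))/sqrt(2).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    zx = (x - x.mean()) / x.std(ddof=1)
    zy = (y - y.mean()) / y.std(ddof=1)
    r = float(np.corrcoef(zx, zy)[0, 1])
    lam1 = 1 + abs(r)
    var_explained = 100.0 * lam1 / 2.0
    v = np.array([1.0, np.sign(r) if r != 0 else 1.0]) / np.sqrt(2)
    scores = zx * v[0] + zy * v[1]
    return scores, var_explained
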