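"""Independent oracles the test suite checks the implementation against.

These deliberately share no code with the package: the LOH oracle is an
exact Markov-chain enumeration over chromatid states, and the
chi-square oracle recomputes expected counts from marginals by hand.
"""

import math
from collections import defaultdict

import numpy as np
from scipy import stats as sps


def loh_central_fusion_oracle(
    distance: float,
    mean_crossovers: float = 2.0,
    chromosome_length: float = 1.0,
    tol: float = 1e-12,
) -> float:
    """Exact central-fusion LOH probability at one heterozygous locus.

    Enumerates the allele configuration of the four chromatids
    (A1, A2 | B1, B2) as a distribution over states. Each crossover hits
    the locus with probability d/L (uniform breakpoints), so the number
    of effective exchanges is Poisson(mean * d/L); an exchange swaps the
    locus allele between one uniformly chosen A-strand and one B-strand.
    LOH is then averaged over the four equally likely chromatid-to-
    central-position assignments (one strand from each meiosis-I pole).
    """
    lam = mean_crossovers * min(distance / chromosome_length, 1.0)

    def step(dist):
        out = defaultdict(float)
        for state, p in dist.items():
            for i in (0, 1):
                for j in (2, 3):
                    s = list(state)
                    s[i], s[j] = s[j], s[i]
                    out[tuple(s)] += p * 0.25
        return dict(out)

    def loh_given(state):
        return sum(state[i] == state[j] for i in (0, 1) for j in (2, 3)) / 4.0

    dist = {(0, 0, 1, 1): 1.0}
    ans, j, cum = 0.0, 0, 0.0
    while cum < 1 - tol and j < 500:
        pj = math.exp(-lam) * lam ** j / math.factorial(j)
        ans += pj * sum(p * loh_given(s) for s, p in dist.items())
        cum += pj
        dist = step(dist)
        j += 1
    return ans


def chisq_brute_force(obs: np.ndarray):
    """Pearson chi-square from first principles: E_ij = R_i C_j / N."""
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    stat = ((obs - expected) ** 2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = sps.chi2.sf(stat, df)
    return stat, df, p
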