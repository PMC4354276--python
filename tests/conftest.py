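import numpy as np
import pytest

from visint.observer import load_profile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nt_profile():
    return load_profile("nt")


@pytest.fixture(scope="session")
def asd_profile():
    return load_profile("asd")


def classical_mixed_anova_oracle(y: np.ndarray, groups, k: int) -> dict:
    """Brute-force balanced mixed-design ANOVA from cell/marginal means.

    ``y`` is an (N subjects x k levels) matrix, ``groups`` the length-N
    group labels.  Returns F, df and partial eta squared for the between
    main effect, within main effect and interaction.  Kept independent of
    the package implementation (used as an oracle in tests).
    """
    y = np.asarray(y, dtype=float)
    n_subj = y.shape[0]
    glabels = sorted(set(groups))
    grand = y.mean()
    level_means = y.mean(axis=0)
    ss_g = ss_sw = ss_int = ss_err = 0.0
    for g in glabels:
        idx = [i for i, gg in enumerate(groups) if gg == g]
        yg = y[idx]
        ng = len(idx)
        gmean = yg.mean()
        glevel = yg.mean(axis=0)
        ss_g += k * ng * (gmean - grand) ** 2
        ss_sw += k * np.sum((yg.mean(axis=1) - gmean) ** 2)
        ss_int += ng * np.sum((glevel - gmean - level_means + grand) ** 2)
        ss_err += np.sum(
            (yg - yg.mean(axis=1, keepdims=True) - glevel + gmean) ** 2
        )
    ss_w = n_subj * np.sum((level_means - grand) ** 2)
    df_g, df_sw = 1, n_subj - 2
    df_w, df_e = k - 1, (k - 1) * (n_subj - 2)
    return {
        "between": {
            "F": (ss_g / df_g) / (ss_sw / df_sw),
            "df": (df_g, df_sw),
            "np2": ss_g / (ss_g + ss_sw),
        },
        "within": {
            "F": (ss_w / df_w) / (ss_err / df_e),
            "df": (df_w, df_e),
            "np2": ss_w / (ss_w + ss_err),
        },
        "interaction": {
            "F": (ss_int / df_w) / (ss_err / df_e),
            "df": (df_w, df_e),
            "np2": ss_int / (ss_int + ss_err),
        },
    }
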