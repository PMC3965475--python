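import numpy as np
import pytest

from lipomet.kinetics import KineticParameters, SizeGrid


@pytest.fixture(scope="session")
def grid() -> SizeGrid:
    return SizeGrid.default()


@pytest.fixture(scope="session")
def three_bin_grid() -> SizeGrid:
    """Coarse all-VLDL grid used by the hand-computable examples."""
    return SizeGrid(
        bin_diameters=np.array([30.0, 45.0, 60.0]),
        subclass_map={"VLDL_small": (0, 1), "VLDL_medium": (1, 2), "VLDL_large": (2, 3)},
        class_ranges={"VLDL_to_LDL": (0, 3), "VLDL_only": (0, 3), "IDL_to_LDL": (0, 0)},
    )


@pytest.fixture(scope="session")
def typical_params() -> KineticParameters:
    """A realistic mid-population parameter set."""
    return KineticParameters(
        f_prod_total=80.0, prod_mu=45.0, prod_sigma=0.25,
        k_lpl=2.0, k_hl=0.15, k_att=0.015, k_upt=0.015,
    )


def random_params(rng: np.random.Generator) -> KineticParameters:
    """Log-normal draw around the default population center."""
    f, mu, sig, lpl, hl, att = np.exp(
        np.log([80.0, 45.0, 0.25, 2.0, 0.15, 0.015])
        + rng.normal(0, [0.3, 0.05, 0.15, 0.3, 0.3, 0.3])
    )
    return KineticParameters(f, mu, sig, lpl, hl, att, att)
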