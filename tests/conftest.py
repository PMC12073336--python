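import pytest

from nutribev import BeverageProduct, generate_market


def make_product(**overrides) -> BeverageProduct:
    """An all-zero non-water sugar-sweetened beverage, overridable per field."""
    base = dict(
        product_id="p0",
        category="sugar_sweetened",
        energy_kj=0.0,
        sugars_g=0.0,
        total_fat_g=0.0,
        satfat_g=0.0,
        salt_g=0.0,
        protein_g=0.0,
        fiber_g=0.0,
        fvl_percent=0.0,
        has_nns=False,
        is_water=False,
    )
    base.update(overrides)
    return BeverageProduct(**base)


@pytest.fixture(scope="session")
def small_market():
    """Deterministic 171-product synthetic market (about 5% scale)."""
    return generate_market(seed=7, scale=0.05)
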