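import numpy as np
import pytest

from forest_csb.harmonize import DeadwoodPiece, PlotMeta, TreeRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def meta_1ha():
    return PlotMeta(
        plot_id="P1", site="S1", forest_type="FT1", management="M1",
        stand_age=80.0, plot_area=1.0, mean_temp=8.0, annual_precip=800.0,
    )


def random_tree(rng, plot_id="P1", height=True) -> TreeRecord:
    dbh = float(rng.uniform(5.0, 80.0))
    return TreeRecord(
        plot_id=plot_id,
        species=f"sp{rng.integers(1, 8)}",
        dbh=dbh,
        height=float(rng.uniform(5.0, 40.0)) if height else None,
        alive=True,
    )


def random_piece(rng, plot_id="P1") -> DeadwoodPiece:
    position = ("log", "snag", "stump")[rng.integers(3)]
    d1 = float(rng.uniform(15.5, 79.0))
    return DeadwoodPiece(
        plot_id=plot_id,
        position=position,
        d1=d1,
        d2=float(d1 * rng.uniform(0.5, 1.0)) if position == "log" else None,
        length=float(rng.uniform(0.5, 12.0)),
        decay_stage=int(rng.integers(1, 6)),
        wood_group=("coniferous", "broadleaved")[rng.integers(2)],
    )
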