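import numpy as np
import pytest

from airshed import (
    AirportLayout,
    CampaignBundle,
    RoadNetwork,
    RoadSegment,
    RunConfig,
    SamplingRecord,
    WindRose,
    generate_campaign,
)

CAMPAIGN_SEED = 1


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def campaign(cfg):
    """Default synthetic campaign (study conditions), shared by the suite."""
    bundle, truth, cov = generate_campaign(cfg, seed=CAMPAIGN_SEED)
    return {"bundle": bundle, "truth": truth, "cov": cov}


def make_toy_bundle(no2=(12.0, 8.0)) -> CampaignBundle:
    """Tiny hand-laid study area: one road per class, full airport block.

    Record T sits exactly on the terminal; record R sits 60 m from the
    straight class-3 road (and >500 m from every other road), so its
    100 m class-3 buffer length is the chord 2*sqrt(100^2 - 60^2) = 160.
    """
    network = RoadNetwork([
        RoadSegment(np.array([[1900.0, 0.0], [1900.0, 2000.0]]), 1, 150_000.0),
        RoadSegment(np.array([[0.0, 1800.0], [2000.0, 1800.0]]), 2, 100_000.0),
        RoadSegment(np.array([[0.0, 1000.0], [2000.0, 1000.0]]), 3, 30_000.0),
        RoadSegment(np.array([[500.0, 0.0], [500.0, 700.0]]), 4, 800.0),
    ])
    airport = AirportLayout(
        terminal=np.array([1200.0, 1060.0]),
        runways={"5/23": np.array([[800.0, 900.0], [1400.0, 1200.0]]),
                 "16/34": np.array([[1000.0, 1200.0], [1100.0, 900.0]])},
        centroid=np.array([1000.0, 1050.0]),
        fence=np.array([[700.0, 850.0], [1500.0, 850.0], [1500.0, 1250.0],
                        [700.0, 1250.0], [700.0, 850.0]]),
    )
    roses = [
        WindRose("S1", np.full(8, 0.125)),
        WindRose("S2", np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 0.0])),
    ]
    records = [
        SamplingRecord("T", 1200.0, 1060.0, "S1", 0, no2[0]),
        SamplingRecord("R", 600.0, 940.0, "S2", 0, no2[1]),
    ]
    bundle = CampaignBundle(network=network, airport=airport, roses=roses,
                            records=records)
    bundle.validate()
    return bundle


@pytest.fixture()
def toy_bundle() -> CampaignBundle:
    return make_toy_bundle()
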