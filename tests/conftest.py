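import numpy as np
import pytest

import taxikit as tk


@pytest.fixture(scope="session")
def geometry():
    return tk.BeadAssayGeometry()  # bead at origin, R=50, three 112-um rings


@pytest.fixture
def straight_track():
    """Cell gliding along +x at 2 um/s for 600 s, starting at the origin."""
    pts = tuple(tk.TrackPoint(t=float(t), x=2.0 * t, y=0.0) for t in range(601))
    return tk.Track(track_id="straight", points=pts)


def make_track(track_id, times, xs, ys):
    pts = tuple(tk.TrackPoint(t=float(t), x=float(x), y=float(y))
                for t, x, y in zip(times, xs, ys))
    return tk.Track(track_id=track_id, points=pts)


@pytest.fixture
def tracks_csv(tmp_path):
    path = tmp_path / "tracks.csv"
    path.write_text(
        "track_id,frame,time_s,x_um,y_um\n"
        "trk1,0,0.0,1.0,2.0\n"
        "trk1,1,1.0,2.0,2.0\n"
    )
    return path


TRACKMATE_XML = """<?xml version="1.0" encoding="UTF-8"?>
<TrackMate version="7.0">
  <Model spatialunits="micron" timeunits="sec">
    <AllSpots nspots="3">
      <SpotsInFrame frame="0">
        <Spot ID="s1" name="ID1" POSITION_X="10.0" POSITION_Y="20.0" POSITION_T="0.0" QUALITY="1.0"/>
        <Spot ID="s3" name="ID3" POSITION_X="99.0" POSITION_Y="99.0" POSITION_T="0.0" QUALITY="1.0"/>
      </SpotsInFrame>
      <SpotsInFrame frame="1">
        <Spot ID="s2" name="ID2" POSITION_X="11.0" POSITION_Y="21.0" POSITION_T="1.0" QUALITY="1.0"/>
      </SpotsInFrame>
    </AllSpots>
    <AllTracks>
      <Track name="Track_0" TRACK_ID="0" NUMBER_SPOTS="2">
        <Edge SPOT_SOURCE_ID="s1" SPOT_TARGET_ID="s2" LINK_COST="1.0"/>
      </Track>
    </AllTracks>
  </Model>
</TrackMate>
"""


@pytest.fixture
def trackmate_xml(tmp_path):
    path = tmp_path / "export.xml"
    path.write_text(TRACKMATE_XML)
    return path


# ---------------------------------------------------------------------------
# shared simulations (module-expensive, computed once per session)

@pytest.fixture(scope="session")
def null_trackset():
    """100 unbiased walkers, 600 s at 1 fps, free-dispersal arena."""
    config = tk.SimulationConfig(arena_radius=2000.0, n_cells=100, seed=1)
    return tk.simulate_tracks(config, tk.scenario_params("control"))


@pytest.fixture(scope="session")
def assay_simulations():
    """Attractant / repellent / control runs in the bead-assay arena."""
    geom = tk.BeadAssayGeometry()
    grad = tk.PointSourceGradient()
    out = {}
    for scenario in ("attractant", "repellent", "control"):
        gradient = None if scenario == "control" else grad
        config = tk.SimulationConfig(geometry=geom, gradient=gradient, seed=3)
        out[scenario] = tk.simulate_tracks(config, tk.scenario_params(scenario))
    return out
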