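import numpy as np
import pytest

from cerebrofsi import (FlowBCs, RheologyParams, WallMaterial, build_channel,
                        build_scenario, channel_flow_oracle,
                        channel_pressure_gradient_for_mean_velocity,
                        default_spec, solve_steady_flow)

CHANNEL_LENGTH = 12e-3
CHANNEL_WIDTH = 3.2e-3
MESH_SIZE = 2e-4
MEAN_V = 0.23


@pytest.fixture(scope="session")
def hb_params():
    return RheologyParams()


@pytest.fixture(scope="session")
def newtonian_params():
    return RheologyParams().newtonian(0.004)


@pytest.fixture(scope="session")
def wall_material():
    return WallMaterial()


@pytest.fixture(scope="session")
def channel_mesh():
    return build_channel(CHANNEL_LENGTH, CHANNEL_WIDTH, MESH_SIZE)


@pytest.fixture(scope="session")
def newtonian_channel_flow(channel_mesh, newtonian_params):
    return solve_steady_flow(channel_mesh, newtonian_params,
                             FlowBCs(inlet_mean_velocity=MEAN_V))


@pytest.fixture(scope="session")
def hb_channel_oracle(hb_params):
    G = channel_pressure_gradient_for_mean_velocity(
        MEAN_V, CHANNEL_WIDTH, hb_params)
    return channel_flow_oracle(G, CHANNEL_WIDTH, hb_params)


@pytest.fixture(scope="session")
def hb_channel_flow(channel_mesh, hb_params, hb_channel_oracle):
    """HB channel solve with the developed oracle profile imposed at inlet."""
    ids = np.unique(channel_mesh.edges_of("INLET"))
    vals = np.zeros((len(ids), 2))
    vals[:, 0] = hb_channel_oracle.profile(channel_mesh.points[ids, 1])
    return solve_steady_flow(channel_mesh, hb_params,
                             FlowBCs(inlet_mean_velocity=MEAN_V),
                             inlet_values=(ids, vals))


@pytest.fixture(scope="session")
def intact_mesh():
    return build_scenario(default_spec("intact"))


@pytest.fixture(scope="session")
def intact_flow(intact_mesh, hb_params):
    return solve_steady_flow(intact_mesh, hb_params)


def interior_wall_mask(mesh, wss, margin=2e-3):
    """Wall samples away from the inlet/outlet ends of the channel."""
    x = mesh.points[wss.node_ids][:, 0]
    return (x > margin) & (x < CHANNEL_LENGTH - margin)
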