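import numpy as np
import pytest
import trimesh

from ficdmap import Bundle, PhantomSpec, SurfaceMesh, make_tensor_phantom


def sphere_mesh(subdivisions: int, radius: float) -> SurfaceMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(ico.vertices), np.asarray(ico.faces))


@pytest.fixture(scope="session")
def small_sphere() -> SurfaceMesh:
    """642-vertex sphere of radius 100 mm (cheap group-statistics mesh)."""
    return sphere_mesh(3, 100.0)


@pytest.fixture(scope="session")
def straight_bundle_volume():
    """60 mm box with one straight FA-0.8 bundle along +x through the center."""
    spec = PhantomSpec(
        grid_shape=(60, 60, 60),
        bundles=[Bundle(np.array([[-29.5, 0.0, 0.0], [29.5, 0.0, 0.0]]), radius=4.0, fa=0.8)],
        mesh_radius=20.0,
    )
    return spec, make_tensor_phantom(spec)


def patch_dice(vertex_ids, patch) -> float:
    inter = len(set(map(int, vertex_ids)) & set(map(int, patch)))
    return 2.0 * inter / (len(vertex_ids) + len(patch))


def assert_units_connected(mesh: SurfaceMesh, parc) -> None:
    """Every cortical unit must be one edge-connected set of faces."""
    neighbors = [[] for _ in range(mesh.n_faces)]
    for a, b in mesh.face_adjacency:
        neighbors[a].append(int(b))
        neighbors[b].append(int(a))
    for cu in parc:
        member = set(map(int, cu.face_ids))
        start = next(iter(member))
        seen = {start}
        stack = [start]
        while stack:
            f = stack.pop()
            for nb in neighbors[f]:
                if nb in member and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        assert len(seen) == len(member), f"CU {cu.id} is disconnected"
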