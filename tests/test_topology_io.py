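"""Topology/coordinate emission, round trips, and run-protocol content."""

import io

import numpy as np
import pytest

import sugarcg as sc
from sugarcg.cg_mapping import assign_beads
from sugarcg.param_fit import ThermoContext, classify_terms, fit_all_terms
from sugarcg.topology_io import (
    make_topology,
    read_gro,
    read_gro_frames,
    read_itp,
    write_gro,
    write_gro_frames,
    write_itp,
    write_run_protocol,
)
from sugarcg.traj_project import build_connectivity, measure_terms

CTX = ThermoContext(300.0)


@pytest.fixture(scope="module")
def trehalose_topology(trehalose_fixture, trehalose_samples):
    _, fx = trehalose_fixture
    fitted = fit_all_terms(trehalose_samples, CTX)
    return make_topology("1GA_0GA", fx.mapping, fx.connectivity,
                         classify_terms(fx.connectivity, fitted))


class TestItp:
    def test_term_counts(self, trehalose_topology):
        assert trehalose_topology.term_counts() == (6, 1, 4, 1, 2)
        assert len(trehalose_topology.beads) == 8

    def test_virtual_sites_massless_and_excluded(self, trehalose_topology):
        vs_ids = [site for site, _ in trehalose_topology.virtual_sites]
        for i in vs_ids:
            assert trehalose_topology.beads[i].mass == 0.0
        excl = dict(trehalose_topology.exclusions)
        for site, cons in trehalose_topology.virtual_sites:
            assert set(excl[site]) == set(cons)

    def test_round_trip_equality(self, trehalose_topology):
        text = write_itp(trehalose_topology)
        assert read_itp(io.StringIO(text)) == trehalose_topology

    def test_malformed_section_reports_line(self, trehalose_topology):
        text = write_itp(trehalose_topology)
        lines = text.splitlines()
        bond_i = next(i for i, l in enumerate(lines)
                      if l.strip() and lines[i - 1].startswith("[ bonds"))
        lines[bond_i + 1] = "    1    2      1  not_a_number  17"
        with pytest.raises(ValueError, match=rf":{bond_i + 2}:"):
            read_itp(io.StringIO("\n".join(lines)))

    def test_counts_invariant_for_all_enumerated_specs(self, all_40_specs):
        from sugarcg.synthetic_fixtures import GeneratorSpec, gen_pseudo_aa_traj

        for spec in all_40_specs[::7]:  # sparse sample; the full set runs elsewhere
            fx = gen_pseudo_aa_traj(GeneratorSpec(spec=spec, n_frames=300, seed=5))
            samples = measure_terms(fx.traj, fx.mapping, fx.connectivity, fx.graph)
            top = make_topology(spec.name, fx.mapping, fx.connectivity,
                                classify_terms(fx.connectivity,
                                               fit_all_terms(samples, CTX)))
            assert top.term_counts() == (6, 1, 4, 1, 2), spec.name

    def test_independent_parser_reads_emitted_file(self, trehalose_topology, tmp_path):
        import warnings

        import MDAnalysis as mda

        path = tmp_path / "mol.itp"
        write_itp(trehalose_topology, path)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            u = mda.Universe(str(path), topology_format="ITP")
        # no warnings about the file's content; MDAnalysis's own notices
        # (coordinate-less itp, element-guessing deprecation) are expected
        allowed = ("No coordinate reader", "elements attribute")
        unexpected = [str(w.message) for w in rec
                      if not any(a in str(w.message) for a in allowed)]
        assert unexpected == []
        assert len(u.atoms) == 8
        assert len(u.bonds) == 7  # 6 constraints + 1 harmonic bond
        assert len(u.angles) == 4
        assert len(u.dihedrals) == 1


class TestGro:
    def test_trehalose_bead_frame_layout(self, trehalose_fixture, tmp_path):
        _, fx = trehalose_fixture
        beads = sc.project_frame(fx.traj.coords[0], fx.mapping, fx.graph)
        names = [b.bead_name for b in fx.mapping.beads]
        resids = [b.residue_index for b in fx.mapping.beads]
        resnames = ["1GA" if r == 1 else "0GA" for r in resids]
        path = tmp_path / "beads.gro"
        write_gro(beads, fx.traj.box, path, names, resnames, resids)
        text = path.read_text().splitlines()
        assert int(text[1]) == 8
        assert len(text) == 2 + 8 + 1

    def test_round_trip_exact_to_3_decimals(self, trehalose_fixture, tmp_path):
        _, fx = trehalose_fixture
        beads = sc.project_frame(fx.traj.coords[0], fx.mapping, fx.graph)
        names = [b.bead_name for b in fx.mapping.beads]
        resids = [b.residue_index for b in fx.mapping.beads]
        path = tmp_path / "beads.gro"
        write_gro(beads, fx.traj.box, path, names, ["MOL"] * 8, resids)
        coords, box, meta = read_gro(path)
        assert coords == pytest.approx(np.round(beads, 3), abs=5.1e-4)
        assert box == pytest.approx(fx.traj.box)
        assert meta["names"] == names

    def test_multiframe_round_trip(self, trehalose_fixture, tmp_path):
        _, fx = trehalose_fixture
        sub = fx.traj.coords[:3]
        names = [n for _, n in fx.graph.atom_order]
        resids = [r for r, _ in fx.graph.atom_order]
        path = tmp_path / "traj.gro"
        write_gro_frames(sub, fx.traj.box, fx.traj.times[:3], path,
                         names, ["GA"] * len(names), resids)
        frames = list(read_gro_frames(path))
        assert len(frames) == 3
        for f, (coords, box, t, _) in enumerate(frames):
            assert coords == pytest.approx(sub[f], abs=5.1e-4)
            assert t == pytest.approx(fx.traj.times[f])


class TestRunProtocol:
    @pytest.mark.parametrize(
        "kind, stage, expects",
        [
            ("simple", "production", {"dt": 0.02, "nsteps": 50_000_000}),
            ("simple", "equilibration", {"dt": 0.02, "nsteps": 5_000_000}),
            ("simple", "minimization", {"integrator": "steep", "nsteps": 500}),
            ("soft", "stage1", {"dt": 0.01, "nsteps": 2_500_000}),
            ("soft", "stage3", {"dt": 0.02, "nsteps": 2_500_000}),
        ],
    )
    def test_stage_settings(self, kind, stage, expects):
        text = write_run_protocol(kind, stage)
        settings = {}
        for line in text.splitlines():
            if "=" in line and not line.startswith(";"):
                k, v = (t.strip() for t in line.split("=", 1))
                settings[k] = v
        for key, val in expects.items():
            assert settings[key] == str(val), (key, settings.get(key))

    def test_nonbonded_treatment_constants(self):
        text = write_run_protocol("simple", "production")
        settings = {}
        for line in text.splitlines():
            if "=" in line and not line.startswith(";"):
                k, v = (t.strip() for t in line.split("=", 1))
                settings[k] = v
        assert settings["coulombtype"] == "reaction-field"
        assert settings["rcoulomb"] == "1.1" and settings["rvdw"] == "1.1"
        assert settings["epsilon_r"] == "15"
        assert settings["ref_t"] == "300"
        assert settings["ref_p"] == "1.0"

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="valid"):
            write_run_protocol("simple", "stage9")
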