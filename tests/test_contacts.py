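"""Typed contact detection, histograms, frequencies, fingerprints, flareplots."""

import numpy as np
import pytest

import biotite.structure as struc

from vnarens.contacts import (
    ContactCriteria,
    contact_frequencies,
    contacts_per_frame,
    detect_contacts,
    fingerprint,
    flareplot_export,
    parse_flareplot,
    records_to_frame,
)
from vnarens.structio import StructureModel
from vnarens.synthetic import build_toy_peptide


def make_structure(atoms_spec, coords):
    """Structure from (atom_name, element, res_name, res_id, chain) tuples."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    arr = struc.AtomArray(len(atoms_spec))
    arr.atom_name = np.array([a[0] for a in atoms_spec])
    arr.element = np.array([a[1] for a in atoms_spec])
    arr.res_name = np.array([a[2] for a in atoms_spec])
    arr.res_id = np.array([a[3] for a in atoms_spec])
    arr.chain_id = np.array([a[4] for a in atoms_spec])
    return StructureModel(stack=struc.from_template(arr, coords))


def salt_bridge_fixture(distance):
    atoms = [
        ("CB", "C", "LYS", 1, "A"), ("NZ", "N", "LYS", 1, "A"),
        ("CB", "C", "GLU", 5, "A"), ("OE1", "O", "GLU", 5, "A"),
    ]
    coords = [[0, 0, 0], [1.5, 0, 0], [1.5 + distance + 3.0, 0, 0],
              [1.5 + distance, 0, 0]]
    return make_structure(atoms, coords)


class TestDetection:
    def test_salt_bridge_threshold(self):
        close = detect_contacts(salt_bridge_fixture(3.5))
        types = {r.contact_type for r in close}
        assert "salt_bridge" in types
        far = detect_contacts(salt_bridge_fixture(6.0))
        assert all(r.contact_type != "salt_bridge" for r in far)

    def test_helix_backbone_hydrogen_bonds(self, helix_octapeptide):
        records = detect_contacts(helix_octapeptide)
        hbonds = {
            (r.res_a, r.res_b)
            for r in records
            if r.contact_type == "hydrogen_bond" and r.atom_a == "O" and r.atom_b == "N"
        }
        # the alpha-helical O(i)...N(i+4) ladder must be present
        for i in range(1, 5):
            assert (i, i + 4) in hbonds

    def test_matches_brute_force_oracle_on_random_fixture(self):
        rng = np.random.default_rng(47)
        torsions = rng.uniform(-180, 180, size=(2, 8, 2))
        pep = build_toy_peptide("AKDESQTN", torsions, side_chain_atoms=True)
        criteria = ContactCriteria()
        records = detect_contacts(pep, criteria)

        # O(n^2) oracle re-deriving every record independently
        from vnarens.contacts import (
            VDW_RADII, DEFAULT_VDW_RADIUS, _atom_table,
        )

        atoms = _atom_table(pep.stack)
        coords = pep.coords
        oracle = set()
        for f in range(coords.shape[0]):
            for i in range(len(atoms)):
                for j in range(i + 1, len(atoms)):
                    ai, aj = atoms[i], atoms[j]
                    if abs(ai["res_id"] - aj["res_id"]) < 2:
                        continue
                    d = float(np.linalg.norm(coords[f, i] - coords[f, j]))
                    ctype = None
                    if ai["charge"] * aj["charge"] < 0 and d <= 4.0:
                        ctype = "salt_bridge"
                    elif d <= 3.5:
                        for don, acc in ((ai, aj), (aj, ai)):
                            if don["donor"] and acc["acceptor"] and don["antecedent"] is not None:
                                v1 = coords[f, don["antecedent"]] - coords[f, don["index"]]
                                v2 = coords[f, acc["index"]] - coords[f, don["index"]]
                                cosang = v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2)
                                if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 110.0:
                                    ctype = "hydrogen_bond"
                                    break
                    if ctype is None and d <= ai["radius"] + aj["radius"] + 0.5:
                        ctype = "vdw"
                    if ctype:
                        oracle.add((f, i, j, ctype))
        mine = set()
        index = {(a["res_id"], a["atom_name"]): a["index"] for a in atoms}
        for r in records:
            i = index[(r.res_a, r.atom_a)]
            j = index[(r.res_b, r.atom_b)]
            mine.add((r.frame, min(i, j), max(i, j), r.contact_type))
        assert mine == oracle

    def test_detection_invariant_under_rigid_motion(self):
        pep = build_toy_peptide(
            "AKDE", np.full((1, 4, 2), [-57.0, -47.0]), side_chain_atoms=True
        )
        records = detect_contacts(pep)
        theta = np.radians(33.0)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]]
        )
        moved_stack = pep.stack.copy()
        moved_stack.coord = pep.coords @ rot.T + np.array([5.0, -3.0, 7.0])
        moved_records = detect_contacts(StructureModel(stack=moved_stack))
        key = lambda rs: [(r.frame, r.res_a, r.res_b, r.atom_a, r.atom_b, r.contact_type) for r in rs]
        assert key(records) == key(moved_records)

    def test_empty_selection_rejected(self, helix_octapeptide):
        with pytest.raises(ValueError):
            detect_contacts(
                helix_octapeptide,
                selection_a=np.zeros(helix_octapeptide.n_atoms, bool),
            )


class TestHistograms:
    def test_bin_width_two_semantics(self):
        # frames with 4, 4, 6, 6 residue-pair contacts -> bins {4-5: 2, 6-7: 2}
        class R:
            def __init__(self, frame, res_a):
                self.frame = frame
                self.chain_a, self.chain_b = "A", "A"
                self.res_a, self.res_b = res_a, res_a + 10

        records = []
        for frame, n in enumerate([4, 4, 6, 6]):
            records += [R(frame, i) for i in range(n)]
        edges, counts, per_frame = contacts_per_frame(records, n_frames=4)
        assert per_frame.tolist() == [4, 4, 6, 6]
        assert counts[edges[:-1] == 4][0] == 2
        assert counts[edges[:-1] == 6][0] == 2

    def test_no_contacts_single_zero_bin(self):
        edges, counts, per_frame = contacts_per_frame([], n_frames=5)
        assert per_frame.tolist() == [0] * 5
        assert counts[0] == 5

    def test_weakened_fixture_shifts_histogram_left(self):
        # same fold, polar residues replaced by alanine: strictly fewer
        # typed contacts per frame on average
        rng = np.random.default_rng(48)
        torsions = np.tile(np.array([-57.0, -47.0]), (5, 8, 1)) + rng.normal(
            0, 8, size=(5, 8, 2)
        )
        strong = build_toy_peptide("KDEQSNTK", torsions, side_chain_atoms=True)
        weak = build_toy_peptide("AAAAAAAA", torsions, side_chain_atoms=True)
        _, _, pf_strong = contacts_per_frame(
            detect_contacts(strong), n_frames=5, level="atom"
        )
        _, _, pf_weak = contacts_per_frame(
            detect_contacts(weak), n_frames=5, level="atom"
        )
        assert pf_weak.mean() < pf_strong.mean()


class TestFrequencies:
    def test_frequency_re_derivable_from_records(self, helix_octapeptide):
        records = detect_contacts(helix_octapeptide)
        table = contact_frequencies(records, n_frames=1)
        for row in table.table.itertuples():
            frames = {
                r.frame
                for r in records
                if {(r.chain_a, r.res_a), (r.chain_b, r.res_b)}
                == {(row.chainA, row.resA), (row.chainB, row.resB)}
                and r.contact_type == row.type
            }
            assert len(frames) / 1 == pytest.approx(row.frequency)

    def test_rigid_ensemble_has_lower_count_variance(self):
        from vnarens.synthetic import emit_torsions, sample_markov_chain

        helix = np.array([-57.0, -47.0])
        other = np.array([-120.0, 130.0])
        n_frames = 12
        states = sample_markov_chain(
            np.array([[0.5, 0.5], [0.5, 0.5]]), n_frames, seed=49
        )
        rng = np.random.default_rng(49)
        noise = rng.normal(0, 5, size=(n_frames, 6, 2))
        rigid_tors = np.tile(helix, (n_frames, 6, 1)) + noise
        flex_tors = np.where(
            states[:, None, None] == 0,
            np.tile(helix, (n_frames, 6, 1)),
            np.tile(other, (n_frames, 6, 1)),
        ) + noise
        seq = "KDEQSN"
        rigid = build_toy_peptide(seq, rigid_tors, side_chain_atoms=True)
        flexible = build_toy_peptide(seq, flex_tors, side_chain_atoms=True)
        _, _, pf_rigid = contacts_per_frame(detect_contacts(rigid), n_frames)
        _, _, pf_flex = contacts_per_frame(detect_contacts(flexible), n_frames)
        assert pf_rigid.var() < pf_flex.var()


class TestFingerprint:
    def _table(self, freqs, label):
        import pandas as pd

        from vnarens.contacts import ContactFrequencyTable

        rows = [
            {"chainA": "A", "resA": i + 1, "chainB": "B", "resB": 100 + i,
             "type": "hydrogen_bond", "frequency": f}
            for i, f in enumerate(freqs)
        ]
        return ContactFrequencyTable(
            table=pd.DataFrame(rows), n_frames=100, label=label
        )

    def test_identical_systems_have_zero_distance(self):
        a = self._table([0.9, 0.6, 0.7], "a")
        b = self._table([0.9, 0.6, 0.7], "b")
        fp = fingerprint([a, b], cutoff=0.5)
        assert np.allclose(fp.frequencies[0], fp.frequencies[1])

    def test_cutoff_retention_semantics(self):
        a = self._table([0.9, 0.4], "a")
        b = self._table([0.1, 0.3], "b")
        fp = fingerprint([a, b], cutoff=0.5)
        # pair 0 retained (max 0.9 >= 0.5), pair 1 dropped (max 0.4 < 0.5)
        assert len(fp.pair_keys) == 1
        assert fp.pair_keys[0][1] == 1

    def test_clustering_matches_naive_agglomeration_oracle(self):
        rng = np.random.default_rng(50)
        freqs = rng.uniform(0.5, 1.0, size=(3, 10))
        tables = [self._table(freqs[s], f"s{s}") for s in range(3)]
        fp = fingerprint(tables, cutoff=0.5)

        # O(p^3) average-linkage oracle on the 10 pair columns
        vectors = {i: freqs[:, i] for i in range(10)}
        clusters = [[i] for i in range(10)]
        merges = []
        while len(clusters) > 1:
            best, pair = np.inf, None
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    d = np.mean(
                        [np.linalg.norm(vectors[a] - vectors[b])
                         for a in clusters[i] for b in clusters[j]]
                    )
                    if d < best:
                        best, pair = d, (i, j)
            i, j = pair
            merges.append((sorted(clusters[i] + clusters[j]), best))
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]
        # scipy linkage heights must reproduce the oracle merge heights
        heights = sorted(h for _, h in merges)
        assert np.allclose(sorted(fp.linkage[:, 2]), heights, atol=1e-10)

    def test_empty_retained_set_is_informative(self):
        a = self._table([0.1, 0.2], "a")
        fp = fingerprint([a], cutoff=0.5)
        assert fp.pair_keys == []
        assert fp.frequencies.shape[1] == 0


class TestFlareplot:
    def test_round_trip_preserves_frequencies(self, tmp_path, helix_octapeptide):
        records = detect_contacts(helix_octapeptide)
        table = contact_frequencies(records, n_frames=1)
        path = tmp_path / "flare.json"
        doc = flareplot_export(table, path=path)
        back = parse_flareplot(path)
        assert back == doc
        assert len(doc["edges"]) == len(table.table)
        exported = {
            (e["source"], e["target"], e["type"]): e["frequency"]
            for e in doc["edges"]
        }
        for row in table.table.itertuples():
            key = (f"{row.chainA}:{row.resA}", f"{row.chainB}:{row.resB}", row.type)
            assert exported[key] == row.frequency

    def test_full_occupancy_edge_gets_top_color_bin(self):
        import pandas as pd

        from vnarens.contacts import ContactFrequencyTable

        table = ContactFrequencyTable(
            table=pd.DataFrame(
                [{"chainA": "A", "resA": 1, "chainB": "B", "resB": 2,
                  "type": "salt_bridge", "frequency": 1.0}]
            ),
            n_frames=10,
        )
        doc = flareplot_export(table)
        assert len(doc["edges"]) == 1
        assert doc["edges"][0]["color_bin"] == 4

    def test_records_table_schema(self, helix_octapeptide):
        records = detect_contacts(helix_octapeptide)
        df = records_to_frame(records)
        assert list(df.columns) == [
            "frame", "chainA", "resA", "chainB", "resB", "type",
            "atomA", "atomB", "distance",
        ]
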