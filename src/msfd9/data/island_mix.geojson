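{
  "type": "Feature",
  "properties": {"name": "island_mix", "note": "synthetic stylized subregion: an open basin with two detached island shelves"},
  "geometry": {
    "type": "MultiPolygon",
    "coordinates": [
      [[[0.0, 36.0], [6.0, 36.0], [6.0, 40.5], [0.0, 40.5], [0.0, 36.0]]],
      [[[6.8, 37.0], [8.2, 37.0], [8.2, 38.1], [6.8, 38.1], [6.8, 37.0]]],
      [[[8.6, 39.0], [9.8, 39.0], [9.8, 40.3], [8.6, 40.3], [8.6, 39.0]]]
    ]
  }
}
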