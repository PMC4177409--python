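{
  "type": "Feature",
  "properties": {"name": "elongated_basin", "note": "synthetic stylized subregion: an elongated semi-enclosed basin"},
  "geometry": {
    "type": "Polygon",
    "coordinates": [[
      [12.3, 41.8], [13.5, 40.0], [16.2, 40.2], [19.8, 44.6],
      [19.0, 45.9], [13.0, 45.6], [12.3, 41.8]
    ]]
  }
}
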