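{"type": "Feature", "properties": {"role": "buffer"}, "geometry": {"type": "Polygon", "coordinates": [[[-7.5, 30.0], [-3.5, 30.0], [-3.5, 36.0], [0.5, 60.0], [-3.5, 60.0], [-7.5, 36.0], [-7.5, 30.0]]]}}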