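# SYNTHETIC stand-in for the GEP-70 prognostic signature.
# The true membership is published separately; replace this file
# (or point --catalog-dir elsewhere) for real analyses.
900001_at
900002_at
900003_at
900004_at
900005_at
900006_at
900007_at
900008_at
900009_at
900010_at
900011_at
900012_at
900013_at
900014_at
900015_at
900016_at
900017_at
900018_at
900019_at
900020_at
900021_at
900022_at
900023_at
900024_at
900025_at
900026_at
900027_at
900028_at
900029_at
900030_at
900031_at
900032_at
900033_at
900034_at
900035_at
900036_at
900037_at
900038_at
900039_at
900040_at
900041_at
900042_at
900043_at
900044_at
900045_at
900046_at
900047_at
900048_at
900049_at
900050_at
900051_at
900052_at
900053_at
900054_at
900055_at
900056_at
900057_at
900058_at
900059_at
900060_at
900061_at
900062_at
900063_at
900064_at
900065_at
900066_at
900067_at
900068_at
900069_at
900070_at
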