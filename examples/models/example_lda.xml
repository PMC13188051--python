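<?xml version='1.0' encoding='utf-8'?>
<qsar_model type="lda" version="1">
  <metadata id="example_lda" endpoint="synthetic toxicity class" units="" group="Examples" subgroup="Synthetic classification">
    <citation>synthetic example classifier</citation>
  </metadata>
  <descriptors>
    <descriptor name="d1" source="supplied" />
    <descriptor name="d2" source="supplied" />
  </descriptors>
  <training>
    <chemical id="a1">
      <value d="d1">-1.4279911547733872</value>
      <value d="d2">0.92917928961270613</value>
      <endpoint>inactive</endpoint>
    </chemical>
    <chemical id="a2">
      <value d="d1">-2.8068938804452475</value>
      <value d="d2">0.58959512633880107</value>
      <endpoint>inactive</endpoint>
    </chemical>
    <chemical id="a3">
      <value d="d1">-2.5668053080087905</value>
      <value d="d2">2.1929555722433891</value>
      <endpoint>inactive</endpoint>
    </chemical>
    <chemical id="a4">
      <value d="d1">-1.3851684310638384</value>
      <value d="d2">2.5792119931122111</value>
      <endpoint>inactive</endpoint>
    </chemical>
    <chemical id="a5">
      <value d="d1">-2.3012439573562613</value>
      <value d="d2">0.051718172439652266</value>
      <endpoint>inactive</endpoint>
    </chemical>
    <chemical id="a6">
      <value d="d1">-2.1925794746407203</value>
      <value d="d2">3.9421752122598397</value>
      <endpoint>inactive</endpoint>
    </chemical>
    <chemical id="a7">
      <value d="d1">-2.4188283610083881</value>
      <value d="d2">2.17059493083483</value>
      <endpoint>inactive</endpoint>
    </chemical>
    <chemical id="a8">
      <value d="d1">-1.837648941178619</value>
      <value d="d2">-0.0028091733384394413</value>
      <endpoint>inactive</endpoint>
    </chemical>
    <chemical id="b1">
      <value d="d1">2.3361558069799475</value>
      <value d="d2">-2.0262522297885894</value>
      <endpoint>active</endpoint>
    </chemical>
    <chemical id="b2">
      <value d="d1">1.8814501598047748</value>
      <value d="d2">-2.8008487419105004</value>
      <endpoint>active</endpoint>
    </chemical>
    <chemical id="b3">
      <value d="d1">1.3671761344881816</value>
      <value d="d2">-0.63639216303174317</value>
      <endpoint>active</endpoint>
    </chemical>
    <chemical id="b4">
      <value d="d1">1.1084315989015945</value>
      <value d="d2">-1.1867919420967641</value>
      <endpoint>active</endpoint>
    </chemical>
    <chemical id="b5">
      <value d="d1">2.8490221613288984</value>
      <value d="d2">-0.60254809828352829</value>
      <endpoint>active</endpoint>
    </chemical>
    <chemical id="b6">
      <value d="d1">0.67825861325423009</value>
      <value d="d2">-0.34584844242296375</value>
      <endpoint>active</endpoint>
    </chemical>
    <chemical id="b7">
      <value d="d1">0.58182249128134234</value>
      <value d="d2">-2.2141754439105394</value>
      <endpoint>active</endpoint>
    </chemical>
    <chemical id="b8">
      <value d="d1">3.7013723390465643</value>
      <value d="d2">-0.44440712282207806</value>
      <endpoint>active</endpoint>
    </chemical>
  </training>
</qsar_model>
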