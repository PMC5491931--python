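<?xml version='1.0' encoding='UTF-8'?>
<pnml xmlns="http://www.pnml.org/version-2009/grammar/pnml">
  <net id="fig1" type="http://www.pnml.org/version-2009/grammar/ptnet">
    <page id="page0">
      <place id="p1"/>
      <place id="p2"/>
      <transition id="t1"/>
      <transition id="t2"/>
      <transition id="t3"/>
      <arc id="a0" source="p1" target="t3"/>
      <arc id="a1" source="p2" target="t2">
        <inscription>
          <text>2</text>
        </inscription>
      </arc>
      <arc id="a2" source="t1" target="p1">
        <inscription>
          <text>3</text>
        </inscription>
      </arc>
      <arc id="a3" source="t1" target="p2">
        <inscription>
          <text>2</text>
        </inscription>
      </arc>
      <arc id="a4" source="t2" target="p1"/>
    </page>
  </net>
</pnml>
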