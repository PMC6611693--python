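# Minimal English stop list for patent text.
a
an
and
are
as
at
be
been
being
by
can
could
did
do
does
for
from
had
has
have
in
into
is
it
its
may
might
not
of
on
or
said
shall
should
such
that
the
their
then
thereby
therefore
thereof
these
they
this
to
was
were
when
where
wherein
which
will
with
would
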